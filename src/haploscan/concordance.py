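"""Concordance of called genotypes against an orthogonal truth set.

The truth set plays the role of an array-genotyped subset assumed to be
error-free.  Discordance compares unphased genotype classes (hom-ref /
het / hom-alt); calls below a GQ threshold are treated as missing, so
raising the threshold trades call rate for accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConcordanceReport", "genotype_concordance", "flag_discordant_samples"]


@dataclass
class ConcordanceReport:
    """Accuracy/call-rate summary plus per-sample discordance.

    ``call_accuracy`` is concordant / compared with missing calls excluded;
    ``call_rate`` counts missing (or GQ-filtered) calls against the number
    of truth genotypes.  The ``het_*`` variants restrict the comparison to
    truth-heterozygous genotypes — the calls hardest to make at low depth.
    """

    call_accuracy: float
    call_rate: float
    het_call_accuracy: float
    het_call_rate: float
    n_compared: int
    n_truth: int
    gq_min: int
    per_sample_discordance: dict[str, float] = field(default_factory=dict)


def genotype_concordance(
    called: np.ndarray,
    truth: np.ndarray,
    sample_ids: list[str],
    gq: np.ndarray | None = None,
    gq_min: int = 0,
) -> ConcordanceReport:
    """Score calls against truth over shared sites and samples.

    ``called`` and ``truth`` are (S, N) alt-dosage matrices over identical
    site and sample axes (-1 = missing); ``gq`` is the per-call genotype
    quality used when ``gq_min > 0``.
    """
    called = np.asarray(called)
    truth = np.asarray(truth)
    if called.shape != truth.shape:
        raise ValueError("called and truth matrices must share shape (sites x samples)")
    truth_known = truth >= 0
    if not np.any(truth_known):
        raise ValueError("no overlapping truth genotypes to compare")
    usable = called >= 0
    if gq_min > 0:
        if gq is None:
            raise ValueError("gq matrix required when gq_min > 0")
        usable &= gq >= gq_min

    def metrics(scope: np.ndarray) -> tuple[float, float]:
        compared = scope & usable
        n_truth = int(scope.sum())
        n_comp = int(compared.sum())
        acc = float((called[compared] == truth[compared]).mean()) if n_comp else float("nan")
        rate = n_comp / n_truth if n_truth else float("nan")
        return acc, rate

    acc, rate = metrics(truth_known)
    het_acc, het_rate = metrics(truth_known & (truth == 1))

    per_sample: dict[str, float] = {}
    for i, sid in enumerate(sample_ids):
        compared = truth_known[:, i] & usable[:, i]
        if compared.sum():
            per_sample[sid] = float((called[compared, i] != truth[compared, i]).mean())

    return ConcordanceReport(
        call_accuracy=acc,
        call_rate=rate,
        het_call_accuracy=het_acc,
        het_call_rate=het_rate,
        n_compared=int((truth_known & usable).sum()),
        n_truth=int(truth_known.sum()),
        gq_min=gq_min,
        per_sample_discordance=per_sample,
    )


def flag_discordant_samples(
    report: ConcordanceReport, max_discordance: float = 0.25
) -> list[str]:
    """Samples whose platform discordance exceeds the threshold.

    The default 0.25 sits midway between a genuinely mixed-up sample
    (~50% discordance, e.g. a swap or contamination) and the bulk error
    level (~2%); flagged samples are excluded from downstream stages.
    """
    return sorted(
        sid for sid, d in report.per_sample_discordance.items() if d > max_discordance
    )
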
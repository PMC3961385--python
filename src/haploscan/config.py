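"""Run configuration: defaults and YAML overlay.

Every analysis threshold defaults to the value used throughout the
pipeline's reference analysis: QD < 5.0 fails, GQ >= 10 defines a
confident genotype, |freqDIFF| >= 0.05 flags a variant, MAF < 0.05 and
per-sample missingness > 0.10 are removed before association, constraint
score > 2 marks conservation, and Bonferroni correction uses 11 tests.
"""

from __future__ import annotations

import copy
from pathlib import Path

from . import io as hio

__all__ = ["DEFAULTS", "merge_config", "load_run_config"]

DEFAULTS: dict = {
    "seed": 1,
    "region": {"scale": "test"},
    "pool": {
        "n_founders": 30,
        "theta_sim": 5.42e-4,
        "class_fractions": [0.365, 0.121, 0.514],
    },
    "cohort": {
        "n_cases": 48,
        "n_controls": 0,
        "n_reference": 174,
        "case_class_or": {"RISK": 1.3},
        "array_truth_fraction": 0.5,
        "array_maf_min": 0.05,
    },
    "depth": {
        "per_amplicon_mean": [25.0, 32.0, 18.0, 22.0, 35.0, 30.0, 12.0, 24.0],
        "sample_scale_dispersion": 0.5,
        "site_dispersion": 0.3,
    },
    "error": {
        "epsilon_base": 0.01,
        "epsilon_homopolymer": 0.05,
        "allelic_bias_sites": {},
    },
    "tracks": {
        "dhsp_fraction": 0.2,
        "enhancer_fraction": 0.15,
        "conserved_in_dhsp": 0.2,
        "conserved_outside": 0.03,
    },
    "caller": {
        "epsilon": 0.01,
        "thresholds": {"QD": 5.0, "FS": 60.0, "RPRS": -8.0},
        "naive": {"min_reads": 3, "min_fraction": 0.2, "hom_fraction": 0.8},
    },
    "concordance": {"gq_min": 10, "max_discordance": 0.25},
    "freq": {"flag_diff": 0.05, "maf_common": 0.1},
    "annotate": {"gerp_min": 2.0},
    "assoc": {"max_missing": 0.10, "min_maf": 0.05, "n_tests": 11},
}


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursive dict overlay; override wins leaf-by-leaf."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_run_config(path: str | Path | None = None) -> dict:
    """Defaults overlaid with an optional YAML file."""
    override = hio.load_config(path) if path else None
    return merge_config(DEFAULTS, override)
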
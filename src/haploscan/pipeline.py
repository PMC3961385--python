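"""Stage orchestration: simulate -> call -> concord -> freqcmp -> haplo ->
annotate -> assoc -> report.

Each stage reads the artefacts of its upstream stages from the output
directory and writes its own as TSV/VCF/BED; a missing upstream artefact
raises a named, actionable error.  All randomness derives from the single
configured seed, so a rerun with the same seed reproduces every artefact
byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from . import worked_examples
from .annotate import (
    AnnotationTrack,
    CandidateRecord,
    conservation_enrichment,
    overlap_annotate,
    select_candidates,
)
from .association import allelic_assoc, bonferroni, qc_filter
from .calling import call_pileups, naive_call_matrix, classify_caller_sets
from .concordance import flag_discordant_samples, genotype_concordance
from .frequencies import allelic_chisq, completeness_check, freq_diff, novelty_flag
from .haplotypes import (
    classify_chromosomes,
    diversity_by_class,
    exclusivity_codes,
    segregation_scan,
)
from .region import build_region, default_region
from .simulate import (
    DepthModel,
    ErrorModel,
    TrackConfig,
    default_tag_spec,
    emit_truth,
    sample_cohort,
    simulate_haplotype_pool,
)

__all__ = ["STAGES", "run_stage", "run_all"]


def _require(outdir: Path, name: str, producer: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise FileNotFoundError(
            f"missing artefact {name!r} in {outdir} — run the {producer!r} stage first"
        )
    return path


def _region_from_cfg(cfg: dict):
    rcfg = cfg["region"]
    if "amplicons" in rcfg:
        return build_region(rcfg)
    return default_region(rcfg.get("scale", "test"))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(outdir: Path, cfg: dict) -> dict:
    seed = int(cfg["seed"])
    region = _region_from_cfg(cfg)
    pcfg, ccfg = cfg["pool"], cfg["cohort"]
    pool = simulate_haplotype_pool(
        region,
        n_founders=int(pcfg["n_founders"]),
        theta_sim=float(pcfg["theta_sim"]),
        tag_spec=default_tag_spec(region),
        seed=seed,
        class_fractions=tuple(pcfg["class_fractions"]),
    )
    cohort = sample_cohort(
        pool,
        n_cases=int(ccfg["n_cases"]),
        n_controls=int(ccfg["n_controls"]),
        n_reference=int(ccfg["n_reference"]),
        seed=seed + 1,
        case_class_or=dict(ccfg["case_class_or"]),
        array_truth_fraction=float(ccfg["array_truth_fraction"]),
        array_maf_min=float(ccfg["array_maf_min"]),
    )
    depth = DepthModel(
        per_amplicon_mean=tuple(cfg["depth"]["per_amplicon_mean"]),
        sample_scale_dispersion=float(cfg["depth"]["sample_scale_dispersion"]),
        site_dispersion=float(cfg["depth"]["site_dispersion"]),
    )
    error = ErrorModel(
        epsilon_base=float(cfg["error"]["epsilon_base"]),
        epsilon_homopolymer=float(cfg["error"]["epsilon_homopolymer"]),
        allelic_bias_sites={int(k): float(v) for k, v in cfg["error"]["allelic_bias_sites"].items()},
    )
    tracks = TrackConfig(
        dhsp_fraction=float(cfg["tracks"]["dhsp_fraction"]),
        enhancer_fraction=float(cfg["tracks"]["enhancer_fraction"]),
        conserved_in_dhsp=float(cfg["tracks"]["conserved_in_dhsp"]),
        conserved_outside=float(cfg["tracks"]["conserved_outside"]),
    )
    paths = emit_truth(
        cohort, region, outdir, seed=seed + 2, depth_model=depth,
        error_model=error, track_config=tracks,
    )
    return {str(k): str(v) for k, v in paths.items()}


def stage_call(outdir: Path, cfg: dict) -> dict:
    pileups = hio.read_pileups(_require(outdir, "pileups.tsv", "simulate"))
    sites = hio.read_sites_table(_require(outdir, "sites.tsv", "simulate"))
    alleles = {int(p): (r, a) for p, r, a in zip(sites["pos"], sites["ref"], sites["alt"])}
    region = _region_from_cfg(cfg)

    callset = call_pileups(
        pileups,
        epsilon=float(cfg["caller"]["epsilon"]),
        thresholds=dict(cfg["caller"]["thresholds"]),
    )
    truth_positions = set(alleles)
    emit_mask = callset.variant_mask | np.isin(callset.positions, sorted(truth_positions))
    idx = np.flatnonzero(emit_mask)
    positions = callset.positions[idx]
    stats_by_pos = {s.pos: s for s in callset.stats}
    ref = np.array([alleles.get(int(p), ("N", "A"))[0] for p in positions], dtype=object)
    alt = np.array([alleles.get(int(p), ("N", "A"))[1] for p in positions], dtype=object)
    filters = []
    info = {"AF": [], "QD": [], "FS": [], "RPRS": []}
    for p in positions:
        p = int(p)
        if p in callset.filter_status:
            ok, reasons = callset.filter_status[p]
            filters.append("PASS" if ok else ";".join(reasons))
        else:
            filters.append("PASS")
        st = stats_by_pos.get(p)
        info["AF"].append(st.alt_af_hat if st else callset.af[callset.positions == p][0])
        info["QD"].append(st.qd if st else np.nan)
        info["FS"].append(st.fs_phred if st else np.nan)
        info["RPRS"].append(st.rp_ranksum if st else np.nan)
    hio.write_vcf(
        outdir / "called.vcf",
        positions,
        ref,
        alt,
        callset.sample_ids,
        genotypes=callset.genotypes[idx],
        gq=callset.gq[idx],
        pl=callset.pl[idx],
        info={k: np.asarray(v, dtype=float) for k, v in info.items()},
        filters=filters,
        qual=callset.qual[idx],
        contig_length=region.length_bp,
    )

    ncfg = cfg["caller"]["naive"]
    n_pos, _, n_geno = naive_call_matrix(
        pileups,
        min_reads=int(ncfg["min_reads"]),
        min_fraction=float(ncfg["min_fraction"]),
        hom_fraction=float(ncfg["hom_fraction"]),
    )
    naive_variants = set(int(p) for p in n_pos[np.any(n_geno > 0, axis=1)])
    hio.atomic_write_text(
        outdir / "naive_sites.tsv",
        "pos\n" + "".join(f"{p + 1}\n" for p in sorted(naive_variants)),
    )

    codes, summary = classify_caller_sets(
        naive_variants, callset.passed_positions(), callset.failed_positions()
    )
    rows = "".join(f"{p + 1}\t{codes[p]}\n" for p in sorted(codes))
    hio.atomic_write_text(outdir / "caller_sets.tsv", "pos\tcode\n" + rows)
    hio.atomic_write_text(
        outdir / "caller_summary.tsv",
        "metric\tvalue\n" + "".join(f"{k}\t{v}\n" for k, v in summary.items()),
    )
    return {"summary": summary, "n_called_sites": int(idx.size)}


def _align(called, truth):
    """Common positions and samples of two VcfData objects."""
    common_pos, ci, ti = np.intersect1d(called.positions, truth.positions, return_indices=True)
    samples = [s for s in truth.sample_ids if s in set(called.sample_ids)]
    c_s = [called.sample_ids.index(s) for s in samples]
    t_s = [truth.sample_ids.index(s) for s in samples]
    cg = called.genotypes[np.ix_(ci, c_s)]
    tg = truth.genotypes[np.ix_(ti, t_s)]
    gq = called.gq[np.ix_(ci, c_s)] if called.gq is not None else None
    return common_pos, samples, cg, tg, gq


def stage_concord(outdir: Path, cfg: dict) -> dict:
    called = hio.read_vcf(_require(outdir, "called.vcf", "call"))
    truth = hio.read_vcf(_require(outdir, "array_truth.vcf", "simulate"))
    _, samples, cg, tg, gq = _align(called, truth)
    gq_min = int(cfg["concordance"]["gq_min"])
    rep_all = genotype_concordance(cg, tg, samples, gq=gq, gq_min=0)
    rep_conf = genotype_concordance(cg, tg, samples, gq=gq, gq_min=gq_min)
    excluded = flag_discordant_samples(rep_all, float(cfg["concordance"]["max_discordance"]))
    lines = ["set\tcall_accuracy\tcall_rate\thet_call_accuracy\thet_call_rate\n"]
    for name, rep in (("all", rep_all), (f"gq>={gq_min}", rep_conf)):
        lines.append(
            f"{name}\t{rep.call_accuracy:.4f}\t{rep.call_rate:.4f}"
            f"\t{rep.het_call_accuracy:.4f}\t{rep.het_call_rate:.4f}\n"
        )
    hio.atomic_write_text(outdir / "concordance.tsv", "".join(lines))
    hio.atomic_write_text(outdir / "excluded_samples.txt", "".join(f"{s}\n" for s in excluded))
    return {
        "all": rep_all,
        "confident": rep_conf,
        "excluded_samples": excluded,
    }


def stage_freqcmp(outdir: Path, cfg: dict) -> dict:
    called = hio.read_vcf(_require(outdir, "called.vcf", "call"))
    panel = hio.read_vcf(_require(outdir, "panel.vcf", "simulate"))
    catalogue = hio.read_catalogue(_require(outdir, "catalogue.tsv", "simulate"))
    excluded = set()
    excl_path = outdir / "excluded_samples.txt"
    if excl_path.exists():
        excluded = set(excl_path.read_text().split())
    keep = [i for i, s in enumerate(called.sample_ids) if s not in excluded]

    panel_freq = {}
    for j, p in enumerate(panel.positions):
        g = panel.genotypes[j]
        g = g[g >= 0]
        if g.size:
            panel_freq[int(p)] = g.sum() / (2 * g.size)

    pass_mask = np.array(
        [f == "PASS" and np.any(called.genotypes[j, keep] > 0) for j, f in enumerate(called.filters)]
    )
    rows = []
    case_variant_pos = set()
    for j in np.flatnonzero(pass_mask):
        p = int(called.positions[j])
        g = called.genotypes[j, keep]
        g = g[g >= 0]
        if g.size == 0:
            continue
        case_alt_n = int(g.sum())
        case_n = 2 * g.size
        case_alt_f = case_alt_n / case_n
        case_variant_pos.add(p)
        ref_alt_f = panel_freq.get(p, 0.0)
        rec = freq_diff(case_alt_f, ref_alt_f, position=p)
        panel_n = 2 * len(panel.sample_ids)
        if rec.minor_allele == "alt":
            a, b = case_alt_n, case_n - case_alt_n
            c = int(round(ref_alt_f * panel_n))
        else:
            a, b = case_n - case_alt_n, case_alt_n
            c = int(round((1 - ref_alt_f) * panel_n))
        rec.chisq, rec.p_value = allelic_chisq(a, b, c, panel_n - c)
        rec.novel = novelty_flag(p, catalogue) == "novel"
        rows.append(rec)

    frame = pd.DataFrame(
        {
            "pos": [r.position + 1 for r in rows],
            "minor_allele": [r.minor_allele for r in rows],
            "maf_case": [round(r.maf_case, 4) for r in rows],
            "maf_ref": [round(r.maf_ref, 4) for r in rows],
            "freq_diff": [round(r.freq_diff, 4) for r in rows],
            "flagged": [r.flagged for r in rows],
            "chisq": [round(r.chisq, 4) for r in rows],
            "p": [round(r.p_value, 4) for r in rows],
            "novel": [r.novel for r in rows],
        }
    )
    tmp = outdir / "freq_compare.tsv.tmp"
    frame.to_csv(tmp, sep="\t", index=False)
    tmp.replace(outdir / "freq_compare.tsv")

    completeness = completeness_check(
        case_variant_pos,
        {p: min(f, 1 - f) for p, f in panel_freq.items() if 0 < f < 1},
        maf_min=float(cfg["freq"]["maf_common"]),
    )
    hio.atomic_write_text(
        outdir / "completeness.txt",
        f"common_variant_completeness\t{'NA' if completeness is None else f'{completeness:.4f}'}\n",
    )
    return {"records": rows, "completeness": completeness}


def _read_tags(outdir: Path):
    tags = pd.read_csv(_require(outdir, "tags.tsv", "simulate"), sep="\t")
    positions = tags["pos"].to_numpy() - 1
    return positions, tags["risk_allele"].to_numpy(), tags["prot_allele"].to_numpy()


def stage_haplo(outdir: Path, cfg: dict) -> dict:
    truth = hio.read_vcf(_require(outdir, "truth.vcf", "simulate"))
    panel = hio.read_vcf(_require(outdir, "panel.vcf", "simulate"))
    tag_pos, risk, prot = _read_tags(outdir)
    region = _region_from_cfg(cfg)
    L = region.length_bp

    tag_idx = np.searchsorted(truth.positions, tag_pos)
    case_haps = truth.haplotypes
    labels = classify_chromosomes(case_haps, tag_idx, risk, prot)

    div = diversity_by_class(case_haps, labels, L)
    lines = ["class\tS\tn\ta_n\ttheta\n"]
    for cls, vals in div.per_class.items():
        lines.append(f"{cls}\t{vals['S']}\t{vals['n']}\t{vals['a_n']:.6f}\t{vals['theta']:.6e}\n")
    if div.overall:
        o = div.overall
        lines.append(f"ALL\t{o['S']}\t{o['n']}\t{o['a_n']:.6f}\t{o['theta']:.6e}\n")
    hio.atomic_write_text(outdir / "diversity.tsv", "".join(lines))

    codes = exclusivity_codes(case_haps, labels)
    lines = [
        "# per axis: 2 = minor allele on that class only; 1 = on that class and others;"
        " 0 = absent from that class; ND = a carrier is unphased\n",
        "pos\trisk_code\tprot_code\n",
    ]
    for p, (rc, pc) in zip(truth.positions, codes):
        lines.append(f"{int(p) + 1}\t{rc}\t{pc}\n")
    hio.atomic_write_text(outdir / "exclusivity.tsv", "".join(lines))

    panel_tag_idx = np.searchsorted(panel.positions, tag_pos)
    panel_labels = classify_chromosomes(panel.haplotypes, panel_tag_idx, risk, prot)
    risk_seg, prot_seg = segregation_scan(panel.haplotypes, panel_labels)
    lines = ["pos\taxis\n"]
    for j in risk_seg:
        lines.append(f"{int(panel.positions[j]) + 1}\trisk\n")
    for j in prot_seg:
        lines.append(f"{int(panel.positions[j]) + 1}\tprot\n")
    hio.atomic_write_text(outdir / "segregation.tsv", "".join(lines))

    counts = {cls: int(np.sum(labels == cls)) for cls in ("RISK", "PROT", "OTHER", "ND")}
    panel_counts = {cls: int(np.sum(panel_labels == cls)) for cls in ("RISK", "PROT", "OTHER", "ND")}
    hio.atomic_write_text(
        outdir / "haplotype_classes.tsv",
        "cohort\tRISK\tPROT\tOTHER\tND\n"
        + f"case\t{counts['RISK']}\t{counts['PROT']}\t{counts['OTHER']}\t{counts['ND']}\n"
        + f"panel\t{panel_counts['RISK']}\t{panel_counts['PROT']}\t{panel_counts['OTHER']}\t{panel_counts['ND']}\n",
    )
    return {
        "class_counts": counts,
        "panel_class_counts": panel_counts,
        "diversity": div,
        "n_risk_segregating": len(risk_seg),
        "n_prot_segregating": len(prot_seg),
    }


def stage_annotate(outdir: Path, cfg: dict) -> dict:
    freq = pd.read_csv(_require(outdir, "freq_compare.tsv", "freqcmp"), sep="\t")
    tracks = {
        "dhsp": AnnotationTrack("dhsp", hio.read_bed(_require(outdir, "dhsp.bed", "simulate"))),
        "enhancer": AnnotationTrack("enhancer", hio.read_bed(_require(outdir, "enhancer.bed", "simulate"))),
        "conserved": AnnotationTrack("conserved", hio.read_bed(_require(outdir, "conserved.bed", "simulate"))),
    }
    positions = [int(p) - 1 for p in freq["pos"]]
    annos = overlap_annotate(positions, tracks)
    enrich = conservation_enrichment(annos)

    lines = ["pos\tdhsp_codes\tenhancer\tgerp\tconserved\n"]
    for a in annos:
        codes = ",".join(sorted(a.dhsp_codes)) or "."
        enh = ",".join(sorted(a.enhancer_flags)) or "."
        gerp = f"{a.gerp_score:.2f}" if a.gerp_score is not None else "."
        lines.append(f"{a.position + 1}\t{codes}\t{enh}\t{gerp}\t{int(a.conserved)}\n")
    hio.atomic_write_text(outdir / "annotations.tsv", "".join(lines))

    records = [
        CandidateRecord(
            position=a.position,
            gerp_score=a.gerp_score,
            in_dhsp=a.in_dhsp,
            in_enhancer=a.in_enhancer,
            freq_diff=float(freq["freq_diff"].iloc[k]),
            novel=bool(freq["novel"].iloc[k]),
        )
        for k, a in enumerate(annos)
    ]
    cands = select_candidates(records, gerp_min=float(cfg["annotate"]["gerp_min"]))
    lines = ["pos\tcriteria\n"]
    for c in cands:
        lines.append(f"{c.position + 1}\t{','.join(c.criteria)}\n")
    hio.atomic_write_text(outdir / "candidates.tsv", "".join(lines))

    def fmt(x):
        return "NA" if x is None else f"{x:.4f}"

    hio.atomic_write_text(
        outdir / "enrichment.tsv",
        "metric\tvalue\n"
        + f"prop_conserved_in_dhsp\t{fmt(enrich['prop_conserved_in_dhsp'])}\n"
        + f"prop_conserved_outside\t{fmt(enrich['prop_conserved_outside'])}\n"
        + f"n_in_dhsp\t{enrich['n_in_dhsp']}\n"
        + f"n_outside\t{enrich['n_outside']}\n",
    )
    return {"enrichment": enrich, "n_candidates": len(cands)}


def stage_assoc(outdir: Path, cfg: dict) -> dict:
    called = hio.read_vcf(_require(outdir, "called.vcf", "call"))
    panel = hio.read_vcf(_require(outdir, "panel.vcf", "simulate"))
    acfg = cfg["assoc"]
    gq_min = int(cfg["concordance"]["gq_min"])

    # affected = sequenced cases (confident calls only); unaffected = the
    # unscreened reference panel when no control cohort was simulated
    case_g = called.genotypes.copy()
    if called.gq is not None:
        case_g[called.gq < gq_min] = -1
    pass_mask = np.array([f == "PASS" for f in called.filters])
    common_pos, ci, pi = np.intersect1d(
        called.positions[pass_mask], panel.positions, return_indices=True
    )
    case_sub = case_g[pass_mask][ci]
    panel_sub = panel.genotypes[pi]
    matrix = np.concatenate([case_sub, panel_sub], axis=1)
    ids = called.sample_ids + panel.sample_ids
    n_case = len(called.sample_ids)

    report, filtered, kept_pos, kept_ids = qc_filter(
        matrix, ids, common_pos,
        max_missing=float(acfg["max_missing"]), min_maf=float(acfg["min_maf"]),
    )
    case_cols = [k for k, s in enumerate(kept_ids) if s in set(called.sample_ids)]
    ctrl_cols = [k for k in range(len(kept_ids)) if k not in set(case_cols)]

    results = []
    for j, p in enumerate(kept_pos):
        def counts(cols):
            g = filtered[j, cols]
            g = g[g >= 0]
            return int(g.sum()), int(2 * g.size - g.sum())

        a_alt, a_ref = counts(case_cols)
        c_alt, c_ref = counts(ctrl_cols)
        # orient to the pooled minor allele
        if (a_alt + c_alt) <= (a_ref + c_ref):
            res = allelic_assoc(a_alt, a_ref, c_alt, c_ref, position=int(p))
        else:
            res = allelic_assoc(a_ref, a_alt, c_ref, c_alt, position=int(p))
        results.append(res)
    n_tests = max(len(results), 1)
    adj = bonferroni([r.p for r in results], n_tests=n_tests)
    for r, pa in zip(results, adj):
        r.p_bonferroni = float(pa)

    lines = ["pos\ta\tb\tc\td\tOR\tci_low\tci_high\tchisq\tp\tp_bonferroni\thaldane\n"]
    for r in results:
        lines.append(
            f"{r.position + 1}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t{r.or_hat:.4f}"
            f"\t{r.ci95[0]:.4f}\t{r.ci95[1]:.4f}\t{r.chisq:.4f}\t{r.p:.4g}"
            f"\t{r.p_bonferroni:.4g}\t{int(r.haldane)}\n"
        )
    hio.atomic_write_text(outdir / "assoc.tsv", "".join(lines))
    hio.atomic_write_text(
        outdir / "qc_report.tsv",
        "metric\tvalue\n"
        + f"excluded_samples\t{len(report.excluded_samples)}\n"
        + f"excluded_variants\t{len(report.excluded_variants)}\n"
        + f"samples_kept\t{report.n_samples_kept}\n"
        + f"variants_kept\t{report.n_variants_kept}\n",
    )
    return {"qc": report, "results": results, "n_case_samples": n_case}


def stage_report(outdir: Path, cfg: dict) -> dict:
    parts = [worked_examples.report_text(), "\n# Synthetic-cohort pipeline summary\n"]
    for name in (
        "caller_summary.tsv",
        "concordance.tsv",
        "completeness.txt",
        "haplotype_classes.tsv",
        "diversity.tsv",
        "enrichment.tsv",
        "qc_report.tsv",
    ):
        path = outdir / name
        if path.exists():
            parts.append(f"\n## {name}\n{path.read_text()}")
    text = "".join(parts)
    hio.atomic_write_text(outdir / "report.txt", text)
    return {"report": str(outdir / "report.txt")}


STAGES = {
    "simulate": stage_simulate,
    "call": stage_call,
    "concord": stage_concord,
    "freqcmp": stage_freqcmp,
    "haplo": stage_haplo,
    "annotate": stage_annotate,
    "assoc": stage_assoc,
    "report": stage_report,
}


def run_stage(stage: str, cfg: dict, outdir: str | Path) -> dict:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return STAGES[stage](outdir, cfg)


def run_all(cfg: dict, outdir: str | Path) -> dict:
    out = {}
    for stage in STAGES:
        out[stage] = run_stage(stage, cfg, outdir)
    return out
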
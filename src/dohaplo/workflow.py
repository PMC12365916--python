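"""End-to-end benchmark orchestration.

One config drives the whole loop the benchmark is built around:
simulate a DO cohort -> impute from read depths at a ladder of
coverages -> filter markers -> reconstruct haplotypes from sequencing
and from array calls -> compare reconstructions (cosine concordance,
discordant regions, IBD classification, crossovers, truth concordance)
-> optionally map eQTL with both platforms.  Every stage's output lands
on disk; a manifest records the seed and a config hash so runs are
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import concordance, eqtl, filters, hmm, impute, io, panel, simulate


@dataclass
class BenchmarkConfig:
    seed: int = 1
    n_samples: int = 4
    n_gen: int = 41
    n_markers: int = 1000
    chrom_length_bp: int = 50_000_000
    coverage_levels: tuple = (1.0, 0.1, 0.05, 0.01, 0.001)
    base_error: float = 0.001
    array_fraction: float = 0.1
    array_call_error: float = 0.005
    ibd_spec: list = field(default_factory=list)
    # filter parameters (min_snps scaled for synthetic chromosomes)
    info_start_cutoff: float = 0.95
    info_step: float = 0.01
    min_snps: int = 200
    hwe_alpha: float = 0.05
    # eQTL stage (optional)
    run_eqtl: bool = False
    n_genes: int = 20
    n_causal: int = 10
    effect_size: float = 1.0
    out_dir: str = "bench_run"

    def validate(self):
        cov = list(self.coverage_levels)
        if any(c <= 0 for c in cov) or cov != sorted(cov, reverse=True):
            raise ValueError("coverage levels must be positive, descending")
        return self

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "coverage_levels" in data:
            data["coverage_levels"] = tuple(data["coverage_levels"])
        return cls(**data).validate()

    def config_hash(self):
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return list(o)


def run_benchmark(config):
    """Run the full benchmark; returns the summary dict.

    Writes, under ``config.out_dir``: the founder panel (TSV + VCF),
    truth mosaics, depths and array calls, per-coverage dosages /
    filter reports / allele probabilities / crossovers / discordant
    regions, IBD segments, optional eQTL catalogs, a summary.json and a
    manifest.json.
    """
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    pnl = simulate.simulate_founder_panel(
        cfg.n_markers, cfg.chrom_length_bp,
        ibd_spec=cfg.ibd_spec, seed=rng.integers(2**31))
    io.write_panel_tsv(pnl, out / "founder_panel.tsv")
    io.write_panel_vcf(pnl, out / "founder_panel.vcf")

    mosaics = simulate.simulate_do_diplotypes(
        pnl, cfg.n_gen, cfg.n_samples, seed=rng.integers(2**31))
    sample_ids = [f"S{i:03d}" for i in range(cfg.n_samples)]
    io.write_mosaics_bed(mosaics, sample_ids, out / "truth_mosaics.bed")
    truth_dose = np.stack([m.dose(pnl) for m in mosaics])

    depths_full = simulate.simulate_read_cohort(
        mosaics, pnl, cfg.coverage_levels[0], cfg.base_error,
        seed=rng.integers(2**31))
    io.write_depths_tsv(depths_full, out / "depths_full")

    n_array = max(2, int(round(cfg.array_fraction * pnl.n_markers)))
    array_idx = panel.select_grid(pnl, n_array)
    array_panel = pnl.subset(array_idx)
    calls = simulate.simulate_array_calls(
        mosaics, pnl, array_idx, cfg.array_call_error,
        seed=rng.integers(2**31))
    io.write_calls_tsv(calls, sample_ids,
                       [f"m{i}" for i in array_idx], out / "array_calls.tsv")
    array_post = hmm.diplotype_posteriors(
        impute.array_emissions(calls, array_panel, cfg.array_call_error),
        array_panel.cm, cfg.n_gen)
    array_probs = hmm.genoprob_to_alleleprob(array_post)
    io.write_alleleprobs_wide(array_probs, array_panel.positions,
                              sample_ids, out / "alleleprobs_array.tsv")

    ibd_segs = panel.find_ibd_segments(pnl)
    io.write_ibd_segments(ibd_segs, out / "ibd_segments.tsv")

    thin_seed = rng.integers(2**31)
    summary = {"coverage": {}, "expected_crossovers":
               simulate.expected_crossovers(cfg.n_gen)}
    eqtl_probs = {}
    for cov in cfg.coverage_levels:
        tag = f"{cov:g}x"
        depths = (depths_full if cov == cfg.coverage_levels[0]
                  else impute.downsample_depths(depths_full, cov, thin_seed))
        gl = impute.genotype_likelihoods(depths, cfg.base_error)
        stats, dip_post = impute.impute_cohort(
            gl, pnl, cfg.n_gen, return_diplotypes=True)
        hard = impute.hard_calls(stats.dose_posteriors)
        hwe_p = filters.hwe_pvalues_from_calls(hard)
        retained, report = filters.adaptive_info_filter(
            stats.info, hwe_p, cfg.info_start_cutoff, cfg.info_step,
            min(cfg.min_snps, pnl.n_markers - 1), cfg.hwe_alpha,
            chrom=pnl.chrom)
        io.write_filter_report(report, out / f"filter_report_{tag}.tsv")
        sub = pnl.subset(retained)
        post = hmm.diplotype_posteriors(
            impute.sequencing_emissions(gl[:, retained], sub),
            sub.cm, cfg.n_gen)
        probs = hmm.genoprob_to_alleleprob(post)
        io.write_alleleprobs_wide(probs, sub.positions, sample_ids,
                                  out / f"alleleprobs_seq_{tag}.tsv")
        if cov == cfg.coverage_levels[0]:
            eqtl_probs["seq"] = (probs, sub)

        paths = hmm.maxmarg_path(post)
        xo_sets = [hmm.locate_crossovers(paths[i], sub.positions,
                                         chrom=pnl.chrom)
                   for i in range(cfg.n_samples)]
        io.write_crossovers(xo_sets, sample_ids,
                            out / f"crossovers_{tag}.tsv")

        arr_interp = np.stack([
            concordance.interpolate_probs(
                array_probs[i], array_panel.positions, sub.positions)
            for i in range(cfg.n_samples)])
        regions_all = []
        track_means = []
        for i in range(cfg.n_samples):
            track = concordance.cosine_track(probs[i], arr_interp[i])
            track_means.append(float(track.mean()))
            regs = concordance.flag_discordant_regions(
                track, sub.positions, sample=sample_ids[i],
                chrom=pnl.chrom)
            regions_all.extend(concordance.classify_discordance_ibd(
                regs, ibd_segs, probs[i], arr_interp[i]))
        io.write_discordant_regions(
            regions_all, out / f"discordant_regions_{tag}.tsv")

        n_exp = len(regions_all)
        summary["coverage"][tag] = {
            "mean_concordance": float(np.mean(track_means)),
            "n_markers_retained": int(report.n_retained),
            "final_info_cutoff": report.final_info_cutoff,
            "mean_crossovers": float(np.mean([x.total for x in xo_sets])),
            "genotype_concordance_vs_truth":
                float((hard == truth_dose).mean()),
            "n_discordant_regions": n_exp,
            "frac_ibd_explained":
                (sum(r.ibd_explained for r in regions_all) / n_exp
                 if n_exp else None),
        }

    if cfg.run_eqtl:
        summary["eqtl"] = _run_eqtl_stage(cfg, pnl, mosaics, eqtl_probs,
                                          array_probs, array_panel,
                                          out, rng)

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default,
                  sort_keys=True)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "stages": ["simulate", "impute", "filter", "reconstruct",
                   "concord", "ibd"] + (["eqtl"] if cfg.run_eqtl else []),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default,
                  sort_keys=True)
    return summary


def _run_eqtl_stage(cfg, pnl, mosaics, eqtl_probs, array_probs,
                    array_panel, out, rng):
    truth = simulate.make_expression_truth(
        pnl, cfg.n_genes, cfg.n_causal, cfg.effect_size,
        seed=rng.integers(2**31))
    counts, sex, gen, _ = simulate.simulate_expression(
        mosaics, pnl, truth, seed=rng.integers(2**31))
    gene_ids = [t.gene_id for t in truth]
    io.write_calls_tsv(counts, [f"S{i:03d}" for i in range(len(mosaics))],
                       gene_ids, out / "expression_counts.tsv")
    keep = eqtl.filter_genes(counts, min_total=0, min_unique=3)
    traits = np.stack([eqtl.rankz(v) for v in eqtl.vst(counts[:, keep]).T],
                      axis=1)
    covar = np.stack([sex, gen], axis=1)
    mids = {gene_ids[g]: truth[g].midpoint_bp for g in keep}
    catalogs = {}
    for name, (probs, sub) in {
            "seq": eqtl_probs["seq"],
            "array": (array_probs, array_panel)}.items():
        lods = eqtl.scan1(traits, probs, covar)
        peaks = []
        for t, g in enumerate(keep):
            peaks.extend(eqtl.find_peaks(
                lods[:, t], sub.positions, chrom=pnl.chrom,
                gene=gene_ids[g]))
        peaks, selected = eqtl.local_eqtl(peaks, mids)
        for p in selected.values():
            t = [gene_ids[g] for g in keep].index(p.gene)
            p.effects = eqtl.allele_effects(
                traits[:, t], probs[:, p.peak_index], covar)
        io.write_peaks_tsv(peaks, out / f"eqtl_peaks_{name}.tsv")
        catalogs[name] = selected
    pairs, un_a, un_b = eqtl.match_eqtl(catalogs["seq"], catalogs["array"])
    cosines = [concordance.cosine_similarity(
        p["peak_a"].effects, p["peak_b"].effects) for p in pairs
        if np.linalg.norm(p["peak_a"].effects) > 0]
    return {
        "n_local_seq": len(catalogs["seq"]),
        "n_local_array": len(catalogs["array"]),
        "n_matched": len(pairs),
        "mean_effect_cosine": float(np.mean(cosines)) if cosines else None,
    }


def validate_outputs(run_dir):
    """Check type invariants of a completed run's on-disk outputs.

    Returns a list of violation strings (empty for a pristine run).
    Raises FileNotFoundError if the manifest is missing.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    violations = []
    try:
        pnl = io.read_panel_tsv(run_dir / "founder_panel.tsv")
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        violations.append(f"founder_panel.tsv: {exc}")
        pnl = None
    if pnl is not None and np.any(np.diff(pnl.positions) <= 0):
        violations.append("founder_panel.tsv: positions not increasing")
    for path in sorted(run_dir.glob("alleleprobs_*.tsv")):
        try:
            probs, _, _ = io.read_alleleprobs_wide(path)
        except Exception as exc:  # noqa: BLE001
            violations.append(f"{path.name}: parse error: {exc}")
            continue
        sums = probs.sum(axis=-1)
        bad = np.argwhere(np.abs(sums - 1) > 1e-4)
        if bad.size:
            s, m = bad[0]
            violations.append(
                f"{path.name}: probability row does not sum to 1 "
                f"(sample {s}, marker {m})")
    for path in sorted(run_dir.glob("discordant_regions_*.tsv")):
        import pandas as pd
        df = pd.read_csv(path, sep="\t", comment="#")
        if len(df) and (df["start"] > df["end"]).any():
            violations.append(f"{path.name}: start > end")
    return violations
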
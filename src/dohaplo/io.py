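"""Plain-text readers and writers for the pipeline's artifacts.

All tabular outputs are TSV; genomic intervals use 1-based inclusive
coordinates (declared in a header comment of every BED-like file).
Founder panels can round-trip through TSV or VCF (one sample column per
founder, GT-only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import FOUNDER_LABELS, AlleleDepthMatrix, FounderHaplotypePanel

COORD_COMMENT = "# coordinates: 1-based inclusive\n"


def write_panel_tsv(panel, path):
    df = pd.DataFrame({"chrom": panel.chrom, "pos": panel.positions,
                       "cm": panel.cm})
    for j, lab in enumerate(panel.founder_labels):
        df[lab] = panel.alleles[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path, chrom_length_bp=0):
    df = pd.read_csv(path, sep="\t")
    alleles = df[list(FOUNDER_LABELS)].to_numpy(dtype=np.uint8)
    pos = df["pos"].to_numpy(dtype=np.int64)
    return FounderHaplotypePanel(
        chrom=str(df["chrom"].iloc[0]), positions=pos,
        cm=df["cm"].to_numpy(dtype=float), alleles=alleles,
        chrom_length_bp=chrom_length_bp or int(pos[-1])).validate()


def write_panel_vcf(panel, path):
    """Founder panel as a minimal GT-only VCF with 8 sample columns."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.founder_labels) + "\n")
        for m in range(panel.n_markers):
            gts = "\t".join(f"{a}/{a}" for a in panel.alleles[m])
            fh.write(f"{panel.chrom}\t{panel.positions[m]}\tm{m}\tA\tG\t.\t"
                     f"PASS\t.\tGT\t{gts}\n")


def read_panel_vcf(path, cm_per_mb=0.5, chrom_length_bp=0):
    from cyvcf2 import VCF
    vcf = VCF(path)
    chrom, pos, rows = None, [], []
    for var in vcf:
        chrom = var.CHROM
        pos.append(var.POS)
        rows.append([g[0] for g in var.genotypes])
    pos = np.asarray(pos, dtype=np.int64)
    return FounderHaplotypePanel(
        chrom=str(chrom), positions=pos, cm=pos * (cm_per_mb / 1e6),
        alleles=np.asarray(rows, dtype=np.uint8),
        chrom_length_bp=chrom_length_bp or int(pos[-1])).validate()


def _matrix_df(values, sample_ids, marker_ids):
    df = pd.DataFrame(values, columns=marker_ids)
    df.insert(0, "sample", sample_ids)
    return df


def write_depths_tsv(depths, prefix):
    _matrix_df(depths.ref, depths.sample_ids, depths.marker_ids).to_csv(
        f"{prefix}.ref.tsv", sep="\t", index=False)
    _matrix_df(depths.alt, depths.sample_ids, depths.marker_ids).to_csv(
        f"{prefix}.alt.tsv", sep="\t", index=False)


def read_depths_tsv(prefix, nominal_coverage=0.0):
    ref = pd.read_csv(f"{prefix}.ref.tsv", sep="\t")
    alt = pd.read_csv(f"{prefix}.alt.tsv", sep="\t")
    return AlleleDepthMatrix(
        ref=ref.drop(columns="sample").to_numpy(dtype=np.int64),
        alt=alt.drop(columns="sample").to_numpy(dtype=np.int64),
        nominal_coverage=nominal_coverage,
        sample_ids=list(ref["sample"]),
        marker_ids=list(ref.columns[1:]))


def write_calls_tsv(calls, sample_ids, marker_ids, path):
    _matrix_df(calls, sample_ids, marker_ids).to_csv(
        path, sep="\t", index=False, na_rep="NA")


def read_calls_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return (df.drop(columns="sample").fillna(-1).to_numpy(dtype=np.int64),
            list(df["sample"]))


def write_mosaics_bed(mosaics, sample_ids, path):
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("chrom\tstart\tend\tsample\thomolog\tfounder\n")
        for sid, mos in zip(sample_ids, mosaics):
            for h, segs in enumerate(mos.homologs):
                for s, e, f in segs:
                    fh.write(f"{mos.chrom}\t{s}\t{e}\t{sid}\t{h}\t"
                             f"{FOUNDER_LABELS[f]}\n")


def write_alleleprobs_wide(probs, positions, sample_ids, path):
    """Compact wide TSV: one row per sample-marker, 8 founder columns."""
    S, M, _ = probs.shape
    df = pd.DataFrame({
        "sample": np.repeat(sample_ids, M),
        "pos": np.tile(positions, S),
    })
    for j, lab in enumerate(FOUNDER_LABELS):
        df[lab] = probs[:, :, j].ravel()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_alleleprobs_wide(path):
    df = pd.read_csv(path, sep="\t")
    samples = list(dict.fromkeys(df["sample"]))
    M = len(df) // len(samples)
    probs = df[list(FOUNDER_LABELS)].to_numpy().reshape(len(samples), M, 8)
    positions = df["pos"].to_numpy()[:M]
    return probs, positions, samples


def write_probs_long(probs, positions, sample_ids, state_labels, path):
    """Long-format probability TSV: sample, marker pos, state, prob."""
    S, M, K = probs.shape
    df = pd.DataFrame({
        "sample": np.repeat(sample_ids, M * K),
        "pos": np.tile(np.repeat(positions, K), S),
        "state": np.tile(state_labels, S * M),
        "prob": probs.ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_ibd_segments(segments, path):
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("chrom\tstart\tend\tpairA\tpairB\tlod\tn_markers\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp}\t{s.end_bp}\t"
                     f"{s.founder_pair[0]}\t{s.founder_pair[1]}\t"
                     f"{s.lod:.4f}\t{s.n_markers}\n")


def write_discordant_regions(regions, path):
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("sample\tchrom\tstart\tend\tn_markers\tmean_cosine\t"
                 "founders_G\tfounders_Q\tibd_explained\tsharing_category\n")
        for r in regions:
            fh.write(f"{r.sample}\t{r.chrom}\t{r.start_bp}\t{r.end_bp}\t"
                     f"{r.n_markers}\t{r.mean_cosine:.4f}\t"
                     f"{''.join(sorted(r.founders_G))}\t"
                     f"{''.join(sorted(r.founders_Q))}\t"
                     f"{int(r.ibd_explained)}\t{r.sharing_category}\n")


def write_crossovers(xo_sets, sample_ids, path):
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write("sample\tchrom\tleft\tright\tn_changes\n")
        for sid, xo in zip(sample_ids, xo_sets):
            for left, right, n in xo.boundaries:
                fh.write(f"{sid}\t{xo.chrom}\t{left}\t{right}\t{n}\n")


def write_filter_report(report, path):
    pd.DataFrame([{
        "chrom": report.chrom, "n_input": report.n_input,
        "n_retained": report.n_retained,
        "final_info_cutoff": report.final_info_cutoff,
        "hwe_alpha": report.hwe_alpha,
        "exhausted": int(report.exhausted),
    }]).to_csv(path, sep="\t", index=False)


def write_peaks_tsv(peaks, path):
    rows = []
    for p in peaks:
        row = {"gene": p.gene, "chrom": p.chrom, "peak_bp": p.peak_bp,
               "lod": round(p.lod, 4), "ci_lo": p.ci_lo, "ci_hi": p.ci_hi,
               "is_local": int(p.is_local)}
        eff = p.effects if p.effects is not None else [float("nan")] * 8
        for j, lab in enumerate(FOUNDER_LABELS):
            row[f"beta_{lab}"] = round(float(eff[j]), 6)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
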
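"""Synthetic tumor/normal RNA-seq + ribosome-profiling data with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: heterozygous tumor-only variants on a monomorphic normal background,
Poisson read depth, binomial allele sampling in the tumor, per-allele A-site
(ribosome footprint) density scaled by a programmable elongation-speed factor,
footprint reads of 28-31 nt with per-length P-site offsets and configurable
frame fidelity, and programmable enrichment of optimality-increasing
synonymous mutations in an "oncogene" set and optimality-decreasing ones in a
"TSG" (tumor suppressor) set.

Everything is in transcript coordinates (0-based, half-open), one isoform per
gene, no splicing or indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    BASES,
    COUNT_COLUMNS,
    write_cds_models,
    write_panel,
    write_transcripts,
    write_tsv,
)

# codon prefixes whose four third-base completions all encode one amino acid,
# so any third-position change within them is synonymous
FOURFOLD_PREFIXES = ("GC", "GG", "CC", "CG", "CT", "GT", "TC", "AC")

_AT = ("A", "T")
_CG = ("C", "G")

# codons that never appear in simulated CDS bodies
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOPS
)


@dataclass
class SimConfig:
    """Parameters of the synthetic tumor/normal dataset.

    Defaults describe the regime the analysis is designed for: ten patients,
    heterozygous tumor variants at allele fraction 0.5, RNA depth ~50x at a
    site, baseline A-site/RNA density 0.5, optimality-increasing mutations
    translated twice as fast (factor 0.5) and optimality-decreasing ones twice
    as slow (factor 2.0), three-fold enrichment of the respective mutation
    classes in oncogenes and TSG, footprint lengths 28-31 nt with P-site
    offsets 12/12/13/13 and 90% frame fidelity.
    """

    n_genes: int = 500
    n_onco: int = 60
    n_tsg: int = 60
    cds_len_range: tuple[int, int] = (300, 2400)
    utr5_len: int = 50
    utr3_len: int = 100
    n_patients: int = 10
    rna_depth: float = 50.0
    rpf_depth: float = 25.0
    tumor_allele_fraction: float = 0.5
    base_density: float | None = None  # default rpf_depth / rna_depth
    speed_factor_optimal: float = 0.5
    speed_factor_nonoptimal: float = 2.0
    mut_rate_per_kb: float = 1.0
    enrich_opt_onco: float = 3.0
    enrich_nonopt_tsg: float = 3.0
    offset_by_length: dict[int, int] = field(
        default_factory=lambda: {28: 12, 29: 12, 30: 13, 31: 13}
    )
    frame_fidelity: float = 0.9
    panel_fraction: float = 0.2
    # fraction of injected synonymous variants that are A<->T / C<->G changes
    # (neither optimality direction applies)
    frac_unclassified: float = 0.05
    # decoy sites exercising the polarization exclusions
    frac_non_ancestral: float = 0.02
    frac_missing_outgroup: float = 0.02
    # RPF read simulation
    rpf_reads_per_gene_per_length: int = 5
    init_peak_weight: float = 0.25  # extra P-site mass on the start codon
    # gene-level translation-efficiency effects of scaled mutation counts
    te_effect_optimal: float = 0.5
    te_effect_nonoptimal: float = -0.5
    te_noise_sd: float = 0.1
    gene_depth_scale: float = 200.0  # mean gene-level RNA reads per kb
    seed: int = 0

    def resolved_base_density(self) -> float:
        if self.base_density is not None:
            return self.base_density
        return self.rpf_depth / self.rna_depth

    def validate(self) -> None:
        """Raise ValueError naming the offending field on any invariant violation."""
        for name in ("n_genes", "n_onco", "n_tsg", "n_patients", "utr5_len", "utr3_len",
                     "rpf_reads_per_gene_per_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_onco + self.n_tsg > self.n_genes:
            raise ValueError("n_onco + n_tsg exceeds n_genes")
        lo, hi = self.cds_len_range
        if lo <= 0 or hi < lo:
            raise ValueError("cds_len_range must be a positive interval")
        if lo % 3 or hi % 3:
            raise ValueError("cds_len_range bounds must be divisible by 3")
        if not 0 < self.tumor_allele_fraction < 1:
            raise ValueError("tumor_allele_fraction must lie in (0, 1)")
        if self.rna_depth <= 0 or self.rpf_depth <= 0:
            raise ValueError("rna_depth and rpf_depth must be > 0")
        if self.resolved_base_density() <= 0:
            raise ValueError("base_density must be > 0")
        if not self.speed_factor_optimal < 1 < self.speed_factor_nonoptimal:
            raise ValueError(
                "speed_factor_optimal must be < 1 < speed_factor_nonoptimal"
            )
        if self.mut_rate_per_kb < 0:
            raise ValueError("mut_rate_per_kb must be >= 0")
        if min(self.enrich_opt_onco, self.enrich_nonopt_tsg) <= 0:
            raise ValueError("enrich_opt_onco and enrich_nonopt_tsg must be > 0")
        for length, off in self.offset_by_length.items():
            if not 0 <= off < length:
                raise ValueError(
                    f"offset_by_length[{length}] must be in [0, {length})"
                )
        if not 0 <= self.frame_fidelity <= 1:
            raise ValueError("frame_fidelity must lie in [0, 1]")
        for name in ("panel_fraction", "frac_unclassified", "frac_non_ancestral",
                     "frac_missing_outgroup", "init_peak_weight"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class Dataset:
    """In-memory bundle returned by :func:`generate_dataset`."""

    config: SimConfig
    transcripts: dict[str, str]
    cds_models: pd.DataFrame
    gene_classes: pd.DataFrame  # gene, class
    site_counts: pd.DataFrame  # one row per (site, patient)
    rpf_reads: pd.DataFrame  # gene, pos5, length, sample, allele
    panel: pd.DataFrame  # gene, pos, ref, alt (0-based)
    gene_counts: pd.DataFrame  # per gene per sample RNA/RPF raw counts
    library_sizes: dict[str, float]
    covariates: pd.DataFrame  # gene, gene_length, dn, expression, gc_content
    truth_variants: pd.DataFrame
    truth_genes: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_transcripts(self.transcripts, outdir / "transcripts.fasta")
        write_cds_models(self.cds_models, outdir / "cds_models.tsv")
        write_tsv(self.gene_classes, outdir / "gene_classes.tsv")
        for patient, sub in self.site_counts.groupby("patient", sort=True):
            write_tsv(
                sub.sort_values(["gene", "pos"]).reset_index(drop=True),
                outdir / f"site_counts_{patient}.tsv",
            )
        write_tsv(self.rpf_reads, outdir / "rpf_reads.tsv")
        write_panel(self.panel, outdir / "panel.tsv")
        write_tsv(self.gene_counts, outdir / "gene_counts.tsv")
        write_tsv(
            pd.DataFrame(
                sorted(self.library_sizes.items()), columns=["library", "size"]
            ),
            outdir / "library_sizes.tsv",
        )
        write_tsv(self.covariates, outdir / "covariates.tsv")
        write_tsv(self.truth_variants, outdir / "truth_variants.tsv")
        write_tsv(self.truth_genes, outdir / "truth_genes.tsv")


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    """ATG + random non-stop codons + TAA."""
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    return ["ATG"] + [_NONSTOP_CODONS[i] for i in body] + ["TAA"]


def _pick_variant_codon(
    rng: np.random.Generator, kind: str
) -> tuple[str, str, str]:
    """Return (codon_prefix, ancestral_third_base, derived_third_base)."""
    prefix = FOURFOLD_PREFIXES[rng.integers(len(FOURFOLD_PREFIXES))]
    if kind == "optimal":
        anc = _AT[rng.integers(2)]
        der = _CG[rng.integers(2)]
    elif kind == "non_optimal":
        anc = _CG[rng.integers(2)]
        der = _AT[rng.integers(2)]
    else:  # unclassified: A<->T or C<->G
        pair = (_AT, _CG)[rng.integers(2)]
        i = rng.integers(2)
        anc, der = pair[i], pair[1 - i]
    return prefix, anc, der


def simulate_allele_site_counts(
    n_sites: int,
    rna_depth: float,
    base_density: float,
    speed_factor: float,
    tumor_allele_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vectorized draw of per-site allele counts for variant sites.

    Normal carries only the ancestral allele; tumor allele split is binomial;
    A-site counts are Poisson with mean RNA-count x base_density x speed
    factor (ancestral factor is 1).
    """
    speed_factor = np.asarray(speed_factor)
    rna_normal = rng.poisson(rna_depth, n_sites)
    rna_tumor = rng.poisson(rna_depth, n_sites)
    rna_tumor_der = rng.binomial(rna_tumor, tumor_allele_fraction)
    rna_tumor_anc = rna_tumor - rna_tumor_der
    rpf_normal = rng.poisson(rna_normal * base_density)
    rpf_tumor_anc = rng.poisson(rna_tumor_anc * base_density)
    rpf_tumor_der = rng.poisson(rna_tumor_der * base_density * speed_factor)
    return pd.DataFrame(
        {
            "rna_normal_anc": rna_normal,
            "rna_tumor_anc": rna_tumor_anc,
            "rna_tumor_der": rna_tumor_der,
            "rpf_normal_anc": rpf_normal,
            "rpf_tumor_anc": rpf_tumor_anc,
            "rpf_tumor_der": rpf_tumor_der,
        }
    )


def simulate_gene_class_counts(
    n_onco: int,
    n_tsg: int,
    n_other: int,
    mut_rate_per_kb: float,
    enrich_opt_onco: float,
    enrich_nonopt_tsg: float,
    cds_len_range: tuple[int, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-gene synonymous-mutation counts by optimality class.

    Baseline expectation per class is ``mut_rate_per_kb x CDS-kb``; the
    optimal class is multiplied by ``enrich_opt_onco`` in oncogenes and the
    non-optimal class by ``enrich_nonopt_tsg`` in TSG.
    """
    n = n_onco + n_tsg + n_other
    classes = np.array(
        ["oncogene"] * n_onco + ["TSG"] * n_tsg + ["other"] * n_other
    )
    lo, hi = cds_len_range
    cds_len = rng.integers(lo // 3, hi // 3 + 1, size=n) * 3
    kb = cds_len / 1000.0
    rate_opt = mut_rate_per_kb * kb * np.where(classes == "oncogene", enrich_opt_onco, 1.0)
    rate_non = mut_rate_per_kb * kb * np.where(classes == "TSG", enrich_nonopt_tsg, 1.0)
    return pd.DataFrame(
        {
            "gene": [f"gene_{i:05d}" for i in range(n)],
            "class": classes,
            "cds_len": cds_len,
            "n_optimal_syn": rng.poisson(rate_opt),
            "n_nonoptimal_syn": rng.poisson(rate_non),
        }
    )


def simulate_te_table(
    n_genes: int,
    beta_optimal: float,
    beta_nonoptimal: float,
    noise_sd: float,
    rng: np.random.Generator,
    mut_rate: float = 2.0,
) -> pd.DataFrame:
    """Gene table for regression recovery: log2 TE fold-change is a linear
    function of the min-max-scaled mutation counts plus Gaussian noise;
    nuisance covariates (length, dN, expression, GC) carry no effect."""
    n_opt = rng.poisson(mut_rate, n_genes)
    n_non = rng.poisson(mut_rate, n_genes)

    def scaled(x: np.ndarray) -> np.ndarray:
        span = x.max() - x.min()
        if span == 0:
            return np.zeros_like(x, dtype=float)
        return 2.0 * (x - x.min()) / span - 1.0

    log2_fc = (
        beta_optimal * scaled(n_opt)
        + beta_nonoptimal * scaled(n_non)
        + rng.normal(0.0, noise_sd, n_genes)
    )
    te_normal = rng.lognormal(0.0, 0.3, n_genes)
    return pd.DataFrame(
        {
            "gene": [f"gene_{i:05d}" for i in range(n_genes)],
            "n_optimal_syn": n_opt,
            "n_nonoptimal_syn": n_non,
            "gene_length": rng.integers(500, 5000, n_genes),
            "dn": rng.gamma(2.0, 0.05, n_genes),
            "expression": rng.lognormal(3.0, 1.0, n_genes),
            "gc_content": rng.uniform(0.35, 0.65, n_genes),
            "te_normal": te_normal,
            "te_tumor": te_normal * np.exp2(log2_fc),
        }
    )


def simulate_rpf_reads(
    cds_models: pd.DataFrame,
    offset_by_length: Mapping[int, int],
    frame_fidelity: float,
    reads_per_gene_per_length: int,
    rng: np.random.Generator,
    init_peak_weight: float = 0.25,
    samples: tuple[str, ...] = ("tumor_P01",),
) -> pd.DataFrame:
    """Footprint reads in transcript coordinates.

    Each read's P-site lands on the start codon with probability
    ``init_peak_weight`` (the initiation pile-up the metagene calibration
    exploits) and otherwise uniformly on a CDS codon; the 5' end sits at
    P-site minus the length-specific offset, shifted +-1 nt with probability
    (1 - frame_fidelity)/2 each.
    """
    lengths = sorted(offset_by_length)
    gene_col: list[np.ndarray] = []
    pos5_col: list[np.ndarray] = []
    len_col: list[np.ndarray] = []
    half = (1.0 - frame_fidelity) / 2.0
    samples_arr = np.asarray(samples)
    for _, gm in cds_models.iterrows():
        n_codons = (gm["cds_end"] - gm["cds_start"]) // 3
        for length in lengths:
            off = offset_by_length[length]
            n = reads_per_gene_per_length
            at_start = rng.random(n) < init_peak_weight
            codon = np.where(at_start, 0, rng.integers(0, n_codons, n))
            pos5 = gm["cds_start"] + 3 * codon - off
            u = rng.random(n)
            pos5 = pos5 + np.where(u < half, -1, np.where(u < 2 * half, 1, 0))
            keep = (pos5 >= 0) & (pos5 + length <= gm["transcript_len"])
            pos5 = pos5[keep].astype(int)
            gene_col.append(np.repeat(gm["gene"], len(pos5)))
            pos5_col.append(pos5)
            len_col.append(np.full(len(pos5), length))
    pos5_all = np.concatenate(pos5_col)
    return pd.DataFrame(
        {
            "gene": np.concatenate(gene_col),
            "pos5": pos5_all,
            "length": np.concatenate(len_col),
            "sample": samples_arr[rng.integers(0, len(samples_arr), len(pos5_all))],
            "allele": ".",
        }
    )


def _gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def generate_dataset(config: SimConfig, outdir: str | Path | None = None) -> Dataset:
    """Generate the full synthetic bundle (and optionally write it to disk)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    base_density = config.resolved_base_density()

    lo, hi = config.cds_len_range
    n = config.n_genes
    classes = (
        ["oncogene"] * config.n_onco
        + ["TSG"] * config.n_tsg
        + ["other"] * (n - config.n_onco - config.n_tsg)
    )
    genes = [f"gene_{i:05d}" for i in range(n)]
    cds_lens = rng.integers(lo // 3, hi // 3 + 1, size=n) * 3
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]

    transcripts: dict[str, str] = {}
    cds_rows = []
    variant_rows = []

    for gi, gene in enumerate(genes):
        cds_len = int(cds_lens[gi])
        n_codons = cds_len // 3
        codons = _random_cds(rng, n_codons)
        cds_start = config.utr5_len
        cds_end = cds_start + cds_len
        kb = cds_len / 1000.0

        rate_opt = config.mut_rate_per_kb * kb * (
            config.enrich_opt_onco if classes[gi] == "oncogene" else 1.0
        )
        rate_non = config.mut_rate_per_kb * kb * (
            config.enrich_nonopt_tsg if classes[gi] == "TSG" else 1.0
        )
        rate_unc = config.mut_rate_per_kb * kb * config.frac_unclassified
        n_opt = rng.poisson(rate_opt)
        n_non = rng.poisson(rate_non)
        n_unc = rng.poisson(rate_unc)
        n_var = n_opt + n_non + n_unc

        # decoy sites exercising the polarization exclusions
        n_nonanc = rng.poisson(config.frac_non_ancestral * max(n_var, 1))
        n_missing = rng.poisson(config.frac_missing_outgroup * max(n_var, 1))

        total = n_var + n_nonanc + n_missing
        usable = np.arange(1, n_codons - 1)  # keep start/stop codons intact
        if total > len(usable):
            total = len(usable)
            n_var = min(n_var, total)
            n_opt = min(n_opt, n_var)
            n_non = min(n_non, n_var - n_opt)
            n_unc = n_var - n_opt - n_non
            n_nonanc = min(n_nonanc, total - n_var)
            n_missing = total - n_var - n_nonanc
        chosen = rng.choice(usable, size=total, replace=False)
        kinds = (
            ["optimal"] * n_opt
            + ["non_optimal"] * n_non
            + ["unclassified"] * n_unc
            + ["non_ancestral_ref"] * n_nonanc
            + ["missing_outgroup"] * n_missing
        )

        for codon_idx, kind in zip(chosen, kinds):
            if kind in ("optimal", "non_optimal", "unclassified"):
                prefix, anc, der = _pick_variant_codon(rng, kind)
                codons[codon_idx] = prefix + anc
                pos = cds_start + 3 * int(codon_idx) + 2
                variant_rows.append(
                    {
                        "gene": gene,
                        "pos": pos,
                        "ancestral": anc,
                        "derived": der,
                        "consequence": "synonymous",
                        "optimality": kind,
                        "patient": patients[rng.integers(len(patients))],
                        "speed_factor": {
                            "optimal": config.speed_factor_optimal,
                            "non_optimal": config.speed_factor_nonoptimal,
                            "unclassified": 1.0,
                        }[kind],
                        "decoy": "",
                    }
                )
            else:
                pos = cds_start + 3 * int(codon_idx) + 2
                anc = codons[codon_idx][2]
                der = BASES[(BASES.index(anc) + 1) % 4]
                variant_rows.append(
                    {
                        "gene": gene,
                        "pos": pos,
                        "ancestral": anc,
                        "derived": der,
                        "consequence": "synonymous",
                        "optimality": "unclassified",
                        "patient": patients[rng.integers(len(patients))],
                        "speed_factor": 1.0,
                        "decoy": kind,
                    }
                )

        utr5 = "".join(BASES[i] for i in rng.integers(0, 4, config.utr5_len))
        utr3 = "".join(BASES[i] for i in rng.integers(0, 4, config.utr3_len))
        transcripts[gene] = utr5 + "".join(codons) + utr3
        cds_rows.append(
            {
                "gene": gene,
                "transcript_len": len(transcripts[gene]),
                "cds_start": cds_start,
                "cds_end": cds_end,
            }
        )

    truth_variants = pd.DataFrame(
        variant_rows,
        columns=["gene", "pos", "ancestral", "derived", "consequence",
                 "optimality", "patient", "speed_factor", "decoy"],
    )
    truth_variants["true_density_ancestral"] = base_density
    truth_variants["true_density_derived"] = base_density * truth_variants["speed_factor"]
    panel_mask = rng.random(len(truth_variants)) < config.panel_fraction
    # decoys never enter the panel (they never reach the strict filter anyway)
    panel_mask &= truth_variants["decoy"] == ""
    truth_variants["in_panel"] = panel_mask

    cds_models = pd.DataFrame(cds_rows)
    gene_classes = pd.DataFrame({"gene": genes, "class": classes})

    # ------------------------------------------------------------------ counts
    # one row per (variant site, patient); vectorized across all rows
    n_var = len(truth_variants)
    n_pat = len(patients)
    n_rows = n_var * n_pat
    base_idx = {b: i for i, b in enumerate(BASES)}
    col_idx = {c: i for i, c in enumerate(COUNT_COLUMNS)}

    anc = truth_variants["ancestral"].map(base_idx).to_numpy()
    der = truth_variants["derived"].map(base_idx).to_numpy()
    anc_r = np.repeat(anc, n_pat)
    der_r = np.repeat(der, n_pat)
    counts_mat = np.zeros((n_rows, len(COUNT_COLUMNS)), dtype=int)

    def _col(assay: str, sample: str, base_i: np.ndarray) -> np.ndarray:
        return col_idx[f"{assay}_{sample}_A"] + base_i

    rows_all = np.arange(n_rows)
    # ancestral-only background for every row
    rna_n = rng.poisson(config.rna_depth, n_rows)
    rna_t = rng.poisson(config.rna_depth, n_rows)
    counts_mat[rows_all, _col("rna", "normal", anc_r)] = rna_n
    counts_mat[rows_all, _col("rpf", "normal", anc_r)] = rng.poisson(rna_n * base_density)
    counts_mat[rows_all, _col("rna", "tumor", anc_r)] = rna_t
    counts_mat[rows_all, _col("rpf", "tumor", anc_r)] = rng.poisson(rna_t * base_density)

    # overwrite carrier rows with heterozygous tumor draws
    pat_of = {p: i for i, p in enumerate(patients)}
    carrier_rows = (
        np.arange(n_var) * n_pat + truth_variants["patient"].map(pat_of).to_numpy()
    )
    cc = simulate_allele_site_counts(
        n_var,
        config.rna_depth,
        base_density,
        truth_variants["speed_factor"].to_numpy(),
        config.tumor_allele_fraction,
        rng,
    )
    counts_mat[carrier_rows, _col("rna", "normal", anc)] = cc["rna_normal_anc"]
    counts_mat[carrier_rows, _col("rpf", "normal", anc)] = cc["rpf_normal_anc"]
    counts_mat[carrier_rows, _col("rna", "tumor", anc)] = cc["rna_tumor_anc"]
    counts_mat[carrier_rows, _col("rna", "tumor", der)] = cc["rna_tumor_der"]
    counts_mat[carrier_rows, _col("rpf", "tumor", anc)] = cc["rpf_tumor_anc"]
    counts_mat[carrier_rows, _col("rpf", "tumor", der)] = cc["rpf_tumor_der"]

    ref_base = truth_variants["ancestral"].to_numpy()
    outgroup_base = np.where(
        truth_variants["decoy"] == "non_ancestral_ref",
        truth_variants["derived"],
        np.where(truth_variants["decoy"] == "missing_outgroup", "N", ref_base),
    )
    site_counts = pd.DataFrame(
        {
            "gene": np.repeat(truth_variants["gene"].to_numpy(), n_pat),
            "pos": np.repeat(truth_variants["pos"].to_numpy(), n_pat),
            "ref": np.repeat(ref_base, n_pat),
            "outgroup": np.repeat(outgroup_base, n_pat),
            "patient": np.tile(np.array(patients), n_var),
        }
    )
    for c, i in col_idx.items():
        site_counts[c] = counts_mat[:, i]

    # ------------------------------------------------------------------- reads
    rpf_reads = simulate_rpf_reads(
        cds_models,
        config.offset_by_length,
        config.frame_fidelity,
        config.rpf_reads_per_gene_per_length,
        rng,
        init_peak_weight=config.init_peak_weight,
        samples=tuple(f"tumor_{p}" for p in patients),
    )

    # ------------------------------------------------------------------- panel
    panel_entries = truth_variants[truth_variants["in_panel"]]
    panel = pd.DataFrame(
        {
            "gene": panel_entries["gene"],
            "pos": panel_entries["pos"],
            "ref": panel_entries["ancestral"],
            "alt": panel_entries["derived"],
        }
    ).reset_index(drop=True)

    # ------------------------------------------------- gene-level TE structure
    per_gene = (
        truth_variants[truth_variants["decoy"] == ""]
        .groupby("gene")["optimality"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(genes, fill_value=0)
    )
    n_opt_g = per_gene.get("optimal", pd.Series(0, index=genes)).to_numpy()
    n_non_g = per_gene.get("non_optimal", pd.Series(0, index=genes)).to_numpy()

    def _scaled(x: np.ndarray) -> np.ndarray:
        span = x.max() - x.min()
        return np.zeros_like(x, float) if span == 0 else 2.0 * (x - x.min()) / span - 1.0

    log2_fc = (
        config.te_effect_optimal * _scaled(n_opt_g)
        + config.te_effect_nonoptimal * _scaled(n_non_g)
        + rng.normal(0.0, config.te_noise_sd, n)
    )
    te_normal = rng.lognormal(0.0, 0.3, n)
    te_tumor = te_normal * np.exp2(log2_fc)
    expression = rng.lognormal(0.0, 0.8, n)
    tlen = cds_models["transcript_len"].to_numpy()
    lam_rna = expression * tlen / 1000.0 * config.gene_depth_scale
    counts = {
        "gene": genes,
        "rna_normal": rng.poisson(lam_rna),
        "rna_tumor": rng.poisson(lam_rna),
    }
    counts["rpf_normal"] = rng.poisson(lam_rna * te_normal * base_density)
    counts["rpf_tumor"] = rng.poisson(lam_rna * te_tumor * base_density)
    gene_counts = pd.DataFrame(counts)
    library_sizes = {
        "rna_normal": float(gene_counts["rna_normal"].sum()),
        "rna_tumor": float(gene_counts["rna_tumor"].sum()),
        "rpf_normal": float(gene_counts["rpf_normal"].sum()),
        "rpf_tumor": float(gene_counts["rpf_tumor"].sum()),
    }

    covariates = pd.DataFrame(
        {
            "gene": genes,
            "gene_length": tlen,
            "dn": rng.gamma(2.0, 0.05, n),
            "expression": expression,
            "gc_content": [_gc_content(transcripts[g]) for g in genes],
        }
    )
    truth_genes = pd.DataFrame(
        {
            "gene": genes,
            "class": classes,
            "cds_len": cds_lens,
            "n_optimal_syn": n_opt_g,
            "n_nonoptimal_syn": n_non_g,
            "te_normal": te_normal,
            "te_tumor": te_tumor,
            "log2_te_fc": log2_fc,
        }
    )

    ds = Dataset(
        config=config,
        transcripts=transcripts,
        cds_models=cds_models,
        gene_classes=gene_classes,
        site_counts=site_counts,
        rpf_reads=rpf_reads,
        panel=panel,
        gene_counts=gene_counts,
        library_sizes=library_sizes,
        covariates=covariates,
        truth_variants=truth_variants,
        truth_genes=truth_genes,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds


# ---------------------------------------------------------------------------
# Worked fixture: 3 genes, 6 variants, exact counts, no sampling.
# ---------------------------------------------------------------------------

FIXTURE_OFFSETS = {28: 12, 29: 12, 30: 13, 31: 13}


def _fixture_seq(utr5: int, n_codons: int, utr3: int,
                 overrides: Mapping[int, str]) -> str:
    codons = ["ATG"] + ["GCT"] * (n_codons - 2) + ["TAA"]
    for idx, codon in overrides.items():
        codons[idx] = codon
    return "A" * utr5 + "".join(codons) + "T" * utr3


def worked_fixture() -> Dataset:
    """Hand-specified 3-gene, 6-variant dataset with exact counts.

    Strict-filter design: v1 and v2 pass all five criteria; v3 fails the
    normal-RNA criterion (coverage 4, which also fails the loose filter) and
    the tumor-RPF allele minimum; v4 fails the normal-RPF coverage; v5 fails
    the tumor-RNA allele minimum; v6 fails only the panel exclusion.
    """
    cds_models = pd.DataFrame(
        [
            {"gene": "g1", "transcript_len": 630, "cds_start": 15, "cds_end": 615},
            {"gene": "g2", "transcript_len": 330, "cds_start": 14, "cds_end": 314},
            {"gene": "g3", "transcript_len": 360, "cds_start": 15, "cds_end": 345},
        ]
    )
    gene_classes = pd.DataFrame(
        {"gene": ["g1", "g2", "g3"], "class": ["oncogene", "TSG", "other"]}
    )
    transcripts = {
        # variant codons are overridden so the ancestral third base matches
        "g1": _fixture_seq(15, 200, 15, {10: "GCT", 50: "GCA"}),
        "g2": _fixture_seq(14, 100, 16, {20: "GCG", 40: "GCC"}),
        "g3": _fixture_seq(15, 110, 15, {30: "GCT", 60: "GCA"}),
    }

    # (gene, pos, anc, der, counts...) -- positions are cds_start + 3*codon + 2
    variants = [
        # name gene  pos anc  der  rnaN  rpfN  rnaT_anc rnaT_der rpfT_anc rpfT_der
        ("v1", "g1", 47, "T", "C", 25, 22, 30, 10, 18, 7),
        ("v2", "g1", 167, "A", "G", 40, 30, 24, 12, 16, 5),
        ("v3", "g2", 76, "G", "T", 4, 25, 30, 10, 20, 2),
        ("v4", "g2", 136, "C", "A", 25, 15, 28, 8, 19, 5),
        ("v5", "g3", 107, "T", "G", 30, 25, 28, 2, 20, 4),
        ("v6", "g3", 197, "A", "C", 26, 21, 22, 9, 15, 6),
    ]
    site_rows = []
    truth_rows = []
    for name, gene, pos, anc, der, rna_n, rpf_n, rna_ta, rna_td, rpf_ta, rpf_td in variants:
        row = {
            "gene": gene,
            "pos": pos,
            "ref": anc,
            "outgroup": anc,
            "patient": "P01",
            **{c: 0 for c in COUNT_COLUMNS},
        }
        row[f"rna_normal_{anc}"] = rna_n
        row[f"rpf_normal_{anc}"] = rpf_n
        row[f"rna_tumor_{anc}"] = rna_ta
        row[f"rna_tumor_{der}"] = rna_td
        row[f"rpf_tumor_{anc}"] = rpf_ta
        row[f"rpf_tumor_{der}"] = rpf_td
        site_rows.append(row)
        opt = (
            "optimal"
            if anc in _AT and der in _CG
            else "non_optimal"
            if anc in _CG and der in _AT
            else "unclassified"
        )
        truth_rows.append(
            {
                "gene": gene,
                "pos": pos,
                "ancestral": anc,
                "derived": der,
                "consequence": "synonymous",
                "optimality": opt,
                "patient": "P01",
                "speed_factor": float("nan"),
                "decoy": "",
                "name": name,
                "in_panel": name == "v6",
            }
        )
    site_counts = pd.DataFrame(site_rows)
    truth_variants = pd.DataFrame(truth_rows)

    panel = pd.DataFrame([{"gene": "g3", "pos": 197, "ref": "A", "alt": "C"}])

    # RPF reads: calibration reads at the start-codon pile-up, plus
    # allele-labelled reads whose A-site covers each variant site, matching
    # the designed footprint count table exactly.
    read_rows = []
    for _, gm in cds_models.iterrows():
        for length, off in FIXTURE_OFFSETS.items():
            for _ in range(15):
                read_rows.append(
                    {"gene": gm["gene"], "pos5": gm["cds_start"] - off,
                     "length": length, "sample": "tumor_P01", "allele": "."}
                )
            for _ in range(3):
                read_rows.append(
                    {"gene": gm["gene"], "pos5": gm["cds_start"] - off + 3,
                     "length": length, "sample": "tumor_P01", "allele": "."}
                )
    for name, gene, pos, anc, der, rna_n, rpf_n, rna_ta, rna_td, rpf_ta, rpf_td in variants:
        pos5 = pos - FIXTURE_OFFSETS[28] - 3  # site at the first A-site base
        for allele, count, sample in (
            (anc, rpf_n, "normal_P01"),
            (anc, rpf_ta, "tumor_P01"),
            (der, rpf_td, "tumor_P01"),
        ):
            for _ in range(count):
                read_rows.append(
                    {"gene": gene, "pos5": pos5, "length": 28,
                     "sample": sample, "allele": allele}
                )
    rpf_reads = pd.DataFrame(read_rows)

    # gene-level counts chosen for round RPKM/TE values at library size 1e6
    gene_counts = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3"],
            "rna_normal": [63, 66, 72],
            "rna_tumor": [63, 132, 72],
            "rpf_normal": [126, 33, 72],
            "rpf_tumor": [252, 33, 72],
        }
    )
    library_sizes = {
        "rna_normal": 1e6,
        "rna_tumor": 1e6,
        "rpf_normal": 1e6,
        "rpf_tumor": 1e6,
    }
    covariates = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3"],
            "gene_length": [630, 330, 360],
            "dn": [0.05, 0.10, 0.08],
            "expression": [1.0, 2.0, 1.5],
            "gc_content": [_gc_content(transcripts[g]) for g in ("g1", "g2", "g3")],
        }
    )
    truth_genes = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3"],
            "class": ["oncogene", "TSG", "other"],
            "cds_len": [600, 300, 330],
            "n_optimal_syn": [2, 0, 2],
            "n_nonoptimal_syn": [0, 2, 0],
            "te_normal": [2.0, 0.5, 1.0],
            "te_tumor": [4.0, 0.25, 1.0],
            "log2_te_fc": [1.0, -1.0, 0.0],
        }
    )

    config = SimConfig(
        n_genes=3, n_onco=1, n_tsg=1, cds_len_range=(300, 600),
        utr5_len=15, utr3_len=15, n_patients=1, seed=0,
        offset_by_length=dict(FIXTURE_OFFSETS),
    )
    return Dataset(
        config=config,
        transcripts=transcripts,
        cds_models=cds_models,
        gene_classes=gene_classes,
        site_counts=site_counts,
        rpf_reads=rpf_reads,
        panel=panel,
        gene_counts=gene_counts,
        library_sizes=library_sizes,
        covariates=covariates,
        truth_variants=truth_variants,
        truth_genes=truth_genes,
    )


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["offset_by_length"] = {int(k): int(v) for k, v in d["offset_by_length"].items()}
    return d
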
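"""Variant polarization, tumor-specific filtering, consequence annotation,
and mutation-spectrum summaries.

Mutation direction is polarized against an outgroup nucleotide: a site is
usable only when the reference base equals the outgroup base, in which case
the reference/outgroup base is the ancestral allele and the single
non-reference base observed in tumor RNA is the derived allele.  Sites where
the reference disagrees with the outgroup, where the outgroup base is
unknown, or where more than one non-reference base is observed are excluded.

Two tumor-specificity tiers are applied on top of polarization:

* loose  — normal RNA coverage >= 5 with zero derived reads; tumor RNA shows
  both alleles (derived fraction strictly below 1).
* strict — five criteria: normal RNA >= 20 with zero derived; normal A-site
  footprint coverage >= 20 with zero derived; tumor RNA >= 20 with both
  alleles >= 3; tumor A-site coverage >= 20 with both alleles >= 3; and the
  site is absent from the known-SNP panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import BASES

POLARIZATION_STATUSES = (
    "polarized",
    "non_ancestral_ref",
    "missing_outgroup",
    "multiallelic",
    "monomorphic",
)

CONSEQUENCES = ("synonymous", "missense", "nonsense", "utr5", "utr3", "noncoding")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_BASE_CHANGES = tuple(
    (a, d) for a in BASES for d in BASES if a != d
)  # the 12 ordered nucleotide changes


def _count_cols(assay: str, sample: str) -> list[str]:
    return [f"{assay}_{sample}_{b}" for b in BASES]


def polarize_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Polarize every site against its outgroup base.

    Adds ``status``, ``ancestral`` and ``derived`` columns.  The derived
    allele is the single non-reference base observed (count > 0) in tumor
    RNA; two or more observed non-reference bases make the site multiallelic,
    none make it monomorphic.
    """
    out = sites.copy()
    tumor_rna = out[_count_cols("rna", "tumor")].to_numpy()
    ref_idx = out["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    nonref = tumor_rna.copy()
    nonref[np.arange(len(out)), ref_idx] = 0
    n_nonref_obs = (nonref > 0).sum(axis=1)
    top_nonref = np.asarray(BASES)[nonref.argmax(axis=1)]

    status = np.where(
        ~out["outgroup"].isin(BASES),
        "missing_outgroup",
        np.where(
            out["outgroup"].to_numpy() != out["ref"].to_numpy(),
            "non_ancestral_ref",
            np.where(
                n_nonref_obs > 1,
                "multiallelic",
                np.where(n_nonref_obs == 0, "monomorphic", "polarized"),
            ),
        ),
    )
    out["status"] = status
    out["ancestral"] = np.where(status == "polarized", out["ref"], "")
    out["derived"] = np.where(status == "polarized", top_nonref, "")
    return out


def polarize(site: pd.Series | dict) -> pd.Series:
    """Single-site convenience wrapper around :func:`polarize_table`."""
    return polarize_table(pd.DataFrame([dict(site)])).iloc[0]


def _allele_counts(df: pd.DataFrame, assay: str, sample: str,
                   allele_col: str) -> np.ndarray:
    mat = df[_count_cols(assay, sample)].to_numpy()
    idx = df[allele_col].map({b: i for i, b in enumerate(BASES)})
    idx = idx.fillna(-1).astype(int).to_numpy()
    vals = np.where(idx >= 0, mat[np.arange(len(df)), idx], 0)
    return vals


def loose_filter(
    variants: pd.DataFrame,
    min_normal_cov: int = 5,
    max_derived_in_normal: int = 0,
) -> pd.Series:
    """Loose tumor-specificity tier (boolean Series aligned to the input).

    Normal RNA coverage >= ``min_normal_cov`` with at most
    ``max_derived_in_normal`` derived reads (default zero, i.e. no mutation
    detected in normal); tumor RNA carries both the ancestral and the derived
    allele, so a 100%-derived tumor site fails.
    """
    pol = variants["status"] == "polarized"
    normal_cov = variants[_count_cols("rna", "normal")].sum(axis=1)
    der_normal = _allele_counts(variants, "rna", "normal", "derived")
    anc_tumor = _allele_counts(variants, "rna", "tumor", "ancestral")
    der_tumor = _allele_counts(variants, "rna", "tumor", "derived")
    ok = (
        pol
        & (normal_cov >= min_normal_cov)
        & (der_normal <= max_derived_in_normal)
        & (anc_tumor >= 1)
        & (der_tumor >= 1)
    )
    return ok.rename("loose_pass")


def strict_filter(
    variants: pd.DataFrame,
    panel: set[tuple[str, int]],
    min_cov: int = 20,
    min_allele: int = 3,
    max_derived_in_normal: int = 0,
) -> pd.Series:
    """Strict (high-confidence) tier: the five-criterion filter.

    1. normal RNA coverage >= ``min_cov`` and no derived reads;
    2. normal A-site footprint coverage >= ``min_cov`` and no derived reads
       in the A-site tri-nucleotide;
    3. tumor RNA coverage >= ``min_cov`` with both alleles >= ``min_allele``;
    4. tumor A-site coverage >= ``min_cov`` with both alleles >= ``min_allele``;
    5. site absent from the known-SNP panel.
    """
    pol = variants["status"] == "polarized"
    c1 = (variants[_count_cols("rna", "normal")].sum(axis=1) >= min_cov) & (
        _allele_counts(variants, "rna", "normal", "derived") <= max_derived_in_normal
    )
    c2 = (variants[_count_cols("rpf", "normal")].sum(axis=1) >= min_cov) & (
        _allele_counts(variants, "rpf", "normal", "derived") <= max_derived_in_normal
    )
    c3 = (
        (variants[_count_cols("rna", "tumor")].sum(axis=1) >= min_cov)
        & (_allele_counts(variants, "rna", "tumor", "ancestral") >= min_allele)
        & (_allele_counts(variants, "rna", "tumor", "derived") >= min_allele)
    )
    c4 = (
        (variants[_count_cols("rpf", "tumor")].sum(axis=1) >= min_cov)
        & (_allele_counts(variants, "rpf", "tumor", "ancestral") >= min_allele)
        & (_allele_counts(variants, "rpf", "tumor", "derived") >= min_allele)
    )
    in_panel = pd.Series(
        list(zip(variants["gene"], variants["pos"])), index=variants.index
    ).isin(panel)
    return (pol & c1 & c2 & c3 & c4 & ~in_panel).rename("strict_pass")


def annotate_table(
    variants: pd.DataFrame,
    cds_models: pd.DataFrame,
    transcripts: dict[str, str],
) -> pd.DataFrame:
    """Assign a consequence to every polarized variant.

    Positions upstream of the CDS are 5' UTR, downstream 3' UTR; within the
    CDS the ancestral and derived codons are translated and compared:
    identical amino acids are synonymous, a stop gained or changed is
    nonsense, anything else is missense.  Transcripts without a CDS model
    are noncoding.  Adds ``consequence``, ``codon_index`` and ``codon_pos``.
    """
    models = cds_models.set_index("gene")
    bad = models[(models["cds_end"] - models["cds_start"]) % 3 != 0]
    if len(bad):
        raise ValueError(f"malformed CDS model (length not divisible by 3): {list(bad.index)}")

    consequence: list[str] = []
    codon_index: list[int] = []
    codon_pos: list[int] = []
    for _, v in variants.iterrows():
        gene, pos = v["gene"], int(v["pos"])
        if gene not in models.index:
            consequence.append("noncoding")
            codon_index.append(-1)
            codon_pos.append(-1)
            continue
        m = models.loc[gene]
        if pos < m["cds_start"]:
            consequence.append("utr5")
            codon_index.append(-1)
            codon_pos.append(-1)
            continue
        if pos >= m["cds_end"]:
            consequence.append("utr3")
            codon_index.append(-1)
            codon_pos.append(-1)
            continue
        if v["status"] != "polarized":
            consequence.append("")
            codon_index.append(-1)
            codon_pos.append(-1)
            continue
        off = pos - int(m["cds_start"])
        ci, cp = divmod(off, 3)
        seq = transcripts[gene]
        codon = seq[m["cds_start"] + 3 * ci : m["cds_start"] + 3 * ci + 3]
        anc_codon = codon[:cp] + v["ancestral"] + codon[cp + 1 :]
        der_codon = codon[:cp] + v["derived"] + codon[cp + 1 :]
        aa_anc = str(Seq(anc_codon).translate())
        aa_der = str(Seq(der_codon).translate())
        if aa_anc == aa_der:
            consequence.append("synonymous")
        elif "*" in (aa_anc, aa_der):
            consequence.append("nonsense")
        else:
            consequence.append("missense")
        codon_index.append(ci)
        codon_pos.append(cp)
    out = variants.copy()
    out["consequence"] = consequence
    out["codon_index"] = codon_index
    out["codon_pos"] = codon_pos
    return out


@dataclass
class SpectrumSummary:
    """Mutation-spectrum summary over polarized variants."""

    change_counts: pd.Series  # indexed by "A>G"-style labels, all 12 classes
    change_fractions: pd.Series
    transition_fraction: float
    consequence_fractions: pd.Series

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.change_counts, "fraction": self.change_fractions}
        ).rename_axis("change")


def spectrum(variants: pd.DataFrame) -> SpectrumSummary:
    """Counts/fractions per ordered base change, transition fraction, and
    consequence fractions; computed over polarized variants only."""
    pol = variants[variants["status"] == "polarized"]
    if pol.empty:
        raise ValueError("spectrum requires at least one polarized variant")
    labels = [f"{a}>{d}" for a, d in _BASE_CHANGES]
    changes = pol["ancestral"] + ">" + pol["derived"]
    counts = changes.value_counts().reindex(labels, fill_value=0)
    fractions = counts / counts.sum()
    ts = sum(
        counts[f"{a}>{d}"] for a, d in _BASE_CHANGES if (a, d) in TRANSITIONS
    )
    transition_fraction = float(ts / counts.sum())
    if "consequence" in pol.columns:
        ann = pol[pol["consequence"].isin(CONSEQUENCES)]
        consequence_fractions = (
            ann["consequence"].value_counts(normalize=True)
            if len(ann)
            else pd.Series(dtype=float)
        )
    else:
        consequence_fractions = pd.Series(dtype=float)
    return SpectrumSummary(
        change_counts=counts,
        change_fractions=fractions,
        transition_fraction=transition_fraction,
        consequence_fractions=consequence_fractions,
    )


def merge_patients(variants: pd.DataFrame) -> pd.DataFrame:
    """Union of per-patient variant sets keyed by (gene, pos, derived).

    The input holds one row per (site, patient); the output holds one row per
    key with a sorted comma-joined ``patients`` presence vector and
    ``n_patients``.  The same site with different derived alleles in
    different patients stays as separate entries.  Non-key columns are taken
    from the first contributing patient.
    """
    pol = variants[variants["status"] == "polarized"].copy()
    if "patient" not in pol.columns:
        pol["patient"] = "P01"
    grouped = pol.groupby(["gene", "pos", "derived"], sort=True)
    first = grouped.head(1).set_index(["gene", "pos", "derived"])
    presence = grouped["patient"].agg(lambda p: ",".join(sorted(set(p))))
    out = first.copy()
    out["patients"] = presence
    out["n_patients"] = grouped["patient"].nunique()
    out = out.drop(columns=["patient"])
    return out.reset_index()
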
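"""Allele-specific A-site density at high-confidence synonymous sites.

A-site density at a site is the A-site footprint count divided by the RNA
count for the same allele in the same sample; higher density means slower
local elongation.  No library-size normalization is applied within a sample:
the two alleles of a heterozygous tumor site come from the same library and
the same trans environment, so their densities are directly comparable.
Cross-sample comparisons (normal vs tumor) are reported but are not
library-size normalized.

Codon-optimality direction of a synonymous change follows the GC-ending
rule: A/T -> C/G increases optimality ("optimal", expected faster), C/G ->
A/T decreases it ("non_optimal", expected slower); A<->T and C<->G changes
are unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_AT = frozenset("AT")
_CG = frozenset("CG")

OPTIMALITY_CLASSES = ("optimal", "non_optimal", "unclassified")

GROUPS = ("normal_ancestral", "tumor_ancestral", "tumor_derived")


def classify_optimality(ancestral: str, derived: str) -> str:
    """Optimality direction of a base change under the GC-ending rule."""
    if ancestral == derived:
        raise ValueError("identical bases do not constitute a mutation")
    if ancestral in _AT and derived in _CG:
        return "optimal"
    if ancestral in _CG and derived in _AT:
        return "non_optimal"
    return "unclassified"


def allele_densities(variants: pd.DataFrame, min_rna: int = 1) -> pd.DataFrame:
    """Per-site, per-allele A-site/RNA densities from raw counts.

    Input rows are strict-pass synonymous variants with their count columns;
    rows whose RNA denominator is below ``min_rna`` for any needed allele are
    dropped (cannot occur after the strict filter, which guarantees >= 3
    reads per tumor allele and >= 20 aggregate).  Returns one record per
    site with the three per-allele densities and the underlying counts.
    """
    recs = []
    n_dropped = 0
    for _, v in variants.iterrows():
        anc, der = v["ancestral"], v["derived"]
        rna_n = v[f"rna_normal_{anc}"]
        rna_ta = v[f"rna_tumor_{anc}"]
        rna_td = v[f"rna_tumor_{der}"]
        if min(rna_n, rna_ta, rna_td) < min_rna:
            n_dropped += 1
            continue
        recs.append(
            {
                "gene": v["gene"],
                "pos": v["pos"],
                "ancestral": anc,
                "derived": der,
                "optimality": classify_optimality(anc, der),
                "rna_normal_ancestral": rna_n,
                "rna_tumor_ancestral": rna_ta,
                "rna_tumor_derived": rna_td,
                "rpf_normal_ancestral": v[f"rpf_normal_{anc}"],
                "rpf_tumor_ancestral": v[f"rpf_tumor_{anc}"],
                "rpf_tumor_derived": v[f"rpf_tumor_{der}"],
                "density_normal_ancestral": v[f"rpf_normal_{anc}"] / rna_n,
                "density_tumor_ancestral": v[f"rpf_tumor_{anc}"] / rna_ta,
                "density_tumor_derived": v[f"rpf_tumor_{der}"] / rna_td,
            }
        )
    out = pd.DataFrame(
        recs,
        columns=[
            "gene", "pos", "ancestral", "derived", "optimality",
            "rna_normal_ancestral", "rna_tumor_ancestral", "rna_tumor_derived",
            "rpf_normal_ancestral", "rpf_tumor_ancestral", "rpf_tumor_derived",
            "density_normal_ancestral", "density_tumor_ancestral",
            "density_tumor_derived",
        ],
    )
    out.attrs["n_dropped_zero_rna"] = n_dropped
    return out


@dataclass
class ComparisonResult:
    """Group comparisons of A-site densities for one optimality class."""

    optimality: str
    n_sites: int
    #: two-sample two-sided KS tests between the three density groups;
    #: cross-sample pairs are not library-size normalized
    ks: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    paired_t: float = np.nan
    paired_p: float = np.nan
    mean_tumor_ancestral: float = np.nan
    mean_tumor_derived: float = np.nan
    #: fraction of sites where the ancestral density exceeds the derived
    frac_ancestral_higher: float = np.nan
    log2_transformed: bool = False

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": f"ks:{a}|{b}",
                "statistic": s,
                "p_value": p,
                "note": "" if a.split("_")[0] == b.split("_")[0]
                else "not library-size normalized",
            }
            for (a, b), (s, p) in self.ks.items()
        ]
        rows.append(
            {
                "comparison": "paired_t:tumor_ancestral|tumor_derived",
                "statistic": self.paired_t,
                "p_value": self.paired_p,
                "note": "",
            }
        )
        return pd.DataFrame(rows)


def compare_groups(
    records: pd.DataFrame,
    optimality: str,
    min_sites: int = 10,
    log2: bool = False,
) -> ComparisonResult:
    """Run the group statistics for one optimality class.

    KS tests (two-sided, two-sample) over the three density distributions,
    and a paired t-test of tumor-ancestral vs tumor-derived density across
    sites.  ``log2=True`` applies log2 to the densities first (off by
    default; the untransformed test is the primary procedure).
    """
    sub = records[records["optimality"] == optimality]
    if len(sub) < min_sites:
        raise ValueError(
            f"insufficient data: {len(sub)} {optimality} sites < min_sites={min_sites}"
        )
    cols = {g: sub[f"density_{g}"].to_numpy(dtype=float) for g in GROUPS}
    if log2:
        cols = {g: np.log2(v + 1e-9) for g, v in cols.items()}
    ks = {}
    pairs = [
        ("normal_ancestral", "tumor_ancestral"),
        ("normal_ancestral", "tumor_derived"),
        ("tumor_ancestral", "tumor_derived"),
    ]
    for a, b in pairs:
        res = stats.ks_2samp(cols[a], cols[b])
        ks[(a, b)] = (float(res.statistic), float(res.pvalue))
    t = stats.ttest_rel(cols["tumor_ancestral"], cols["tumor_derived"])
    diff = cols["tumor_ancestral"] - cols["tumor_derived"]
    return ComparisonResult(
        optimality=optimality,
        n_sites=len(sub),
        ks=ks,
        paired_t=float(t.statistic),
        paired_p=float(t.pvalue),
        mean_tumor_ancestral=float(cols["tumor_ancestral"].mean()),
        mean_tumor_derived=float(cols["tumor_derived"].mean()),
        frac_ancestral_higher=float((diff > 0).mean()),
        log2_transformed=log2,
    )
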
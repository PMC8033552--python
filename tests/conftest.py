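import numpy as np
import pandas as pd
import pytest

from synoribo.simulate import SimConfig, generate_dataset, worked_fixture


@pytest.fixture(scope="session")
def fixture_ds():
    """The hand-specified 3-gene, 6-variant worked dataset."""
    return worked_fixture()


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset shared across tests (read-only)."""
    cfg = SimConfig(n_genes=120, n_onco=15, n_tsg=15, n_patients=3, seed=11)
    return generate_dataset(cfg)


def densities_from_counts(counts: pd.DataFrame, optimality: str) -> pd.DataFrame:
    """Build allele-density records straight from generator count draws."""
    ok = (counts[["rna_normal_anc", "rna_tumor_anc", "rna_tumor_der"]] > 0).all(axis=1)
    c = counts[ok]
    return pd.DataFrame(
        {
            "optimality": optimality,
            "density_normal_ancestral": c["rpf_normal_anc"] / c["rna_normal_anc"],
            "density_tumor_ancestral": c["rpf_tumor_anc"] / c["rna_tumor_anc"],
            "density_tumor_derived": c["rpf_tumor_der"] / c["rna_tumor_der"],
        }
    )


def brute_force_strict(variants: pd.DataFrame, panel: set[tuple[str, int]],
                       min_cov: int = 20, min_allele: int = 3) -> set:
    """Independent re-application of the five strict criteria, row by row.

    Deliberately written as explicit per-row scalar checks so it shares no
    code path with the vectorized implementation.
    """
    passed = set()
    for _, v in variants.iterrows():
        if v["status"] != "polarized":
            continue
        anc, der = v["ancestral"], v["derived"]
        rna_normal = sum(v[f"rna_normal_{b}"] for b in "ACGT")
        rpf_normal = sum(v[f"rpf_normal_{b}"] for b in "ACGT")
        rna_tumor = sum(v[f"rna_tumor_{b}"] for b in "ACGT")
        rpf_tumor = sum(v[f"rpf_tumor_{b}"] for b in "ACGT")
        c1 = rna_normal >= min_cov and v[f"rna_normal_{der}"] == 0
        c2 = rpf_normal >= min_cov and v[f"rpf_normal_{der}"] == 0
        c3 = (rna_tumor >= min_cov and v[f"rna_tumor_{anc}"] >= min_allele
              and v[f"rna_tumor_{der}"] >= min_allele)
        c4 = (rpf_tumor >= min_cov and v[f"rpf_tumor_{anc}"] >= min_allele
              and v[f"rpf_tumor_{der}"] >= min_allele)
        c5 = (v["gene"], v["pos"]) not in panel
        if c1 and c2 and c3 and c4 and c5:
            passed.add((v["gene"], v["pos"], v.get("patient", "")))
    return passed
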
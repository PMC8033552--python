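"""End-to-end orchestration: ingestion -> variants -> offsets -> densities ->
gene level, with stage telemetry and a structured report.

The same staged run serves two entry points: :func:`run_all` executes the
pipeline on a dataset bundle (read from disk or freshly simulated) and writes
tables plus a JSON report; :func:`simulate_and_validate` generates synthetic
data with known ground truth, runs the pipeline, and checks every recovered
quantity (offsets, filter set, optimality calls, density directions,
enrichment directions, regression signs) against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import density as density_mod
from . import genes as genes_mod
from . import variants as variants_mod
from .io import read_cds_models, read_panel, read_site_counts, read_transcripts, read_tsv, write_tsv
from .offsets import PsiteOffsetModel
from .simulate import Dataset, SimConfig, generate_dataset, worked_fixture


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run.

    Input paths may be omitted when ``simulate`` is set, in which case the
    dataset is generated from ``sim`` first.  Thresholds mirror the two
    filter tiers (loose coverage 5, strict coverage 20, allele minimum 3)
    and the metagene calibration (window -40..+10, >= 200 reads per length).
    """

    outdir: str = "synoribo_out"
    # inputs (real-data mode)
    counts: list[str] = field(default_factory=list)
    cds: str | None = None
    fasta: str | None = None
    panel: str | None = None
    reads: str | None = None
    gene_counts: str | None = None
    library_sizes: str | None = None
    classes: str | None = None
    covariates: str | None = None
    # synthetic mode
    simulate: bool = False
    sim: SimConfig | None = None
    # thresholds
    loose_min_cov: int = 5
    strict_min_cov: int = 20
    min_allele: int = 3
    max_derived_in_normal: int = 0
    window: tuple[int, int] = (-40, 10)
    min_reads: int = 200
    min_peak_ratio: float = 2.0
    min_frame_conc: float = 0.6
    # statistics
    log2_density: bool = False
    min_sites: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.loose_min_cov <= 0 or self.strict_min_cov <= 0 or self.min_allele <= 0:
            raise ValueError("coverage and allele thresholds must be positive")
        if self.loose_min_cov > self.strict_min_cov:
            raise ValueError("loose_min_cov must be <= strict_min_cov")
        if self.min_reads <= 0:
            raise ValueError("min_reads must be positive")
        if not self.simulate:
            needed = {"counts": self.counts, "cds": self.cds, "fasta": self.fasta}
            for name, val in needed.items():
                if not val:
                    raise ValueError(f"input '{name}' required unless simulate=true")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            off = sim_raw.pop("offset_by_length", None)
            sim = SimConfig(**sim_raw)
            if off is not None:
                sim.offset_by_length = {int(k): int(v) for k, v in off.items()}
            cfg.sim = sim
        if isinstance(cfg.window, list):
            cfg.window = tuple(cfg.window)
        return cfg


def load_dataset(cfg: PipelineConfig) -> Dataset:
    """Read the input bundle from disk (real-data mode)."""
    site_counts = read_site_counts(cfg.counts)
    lib = {}
    if cfg.library_sizes:
        t = read_tsv(cfg.library_sizes)
        lib = dict(zip(t["library"], t["size"].astype(float)))
    return Dataset(
        config=cfg.sim,
        transcripts=read_transcripts(cfg.fasta),
        cds_models=read_cds_models(cfg.cds),
        gene_classes=read_tsv(cfg.classes) if cfg.classes else pd.DataFrame(columns=["gene", "class"]),
        site_counts=site_counts,
        rpf_reads=read_tsv(cfg.reads) if cfg.reads else pd.DataFrame(
            columns=["gene", "pos5", "length", "sample", "allele"]
        ),
        panel=pd.DataFrame(columns=["gene", "pos", "ref", "alt"]),
        gene_counts=read_tsv(cfg.gene_counts) if cfg.gene_counts else pd.DataFrame(),
        library_sizes=lib,
        covariates=read_tsv(cfg.covariates) if cfg.covariates else pd.DataFrame(),
        truth_variants=pd.DataFrame(),
        truth_genes=pd.DataFrame(),
    )


def _panel_set(cfg: PipelineConfig, ds: Dataset) -> set[tuple[str, int]]:
    if cfg.panel:
        return read_panel(cfg.panel)
    if len(ds.panel):
        return set(zip(ds.panel["gene"], ds.panel["pos"]))
    return set()


def _stage(report: dict, outdir: Path, name: str):
    """Context helper: record failures with a marker file."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / f"FAILED_{name}.marker").write_text(str(exc))
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_all(cfg: PipelineConfig, dataset: Dataset | None = None) -> dict:
    """Execute every stage and write the report bundle under ``cfg.outdir``.

    Returns the report dict (also written as ``report.json``).  Any stage
    error aborts the run with :class:`PipelineError`; partial outputs are
    retained next to a ``FAILED_<stage>.marker`` file.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": cfg.seed}

    with _stage(report, outdir, "ingest"):
        if dataset is not None:
            ds = dataset
        elif cfg.simulate:
            sim = cfg.sim or SimConfig(seed=cfg.seed)
            ds = generate_dataset(sim, outdir / "sim")
        else:
            ds = load_dataset(cfg)
        panel = _panel_set(cfg, ds)
        report["stages"]["ingest"] = {
            "n_site_rows": int(len(ds.site_counts)),
            "n_genes": int(len(ds.cds_models)),
            "n_reads": int(len(ds.rpf_reads)),
            "n_panel_sites": len(panel),
        }

    with _stage(report, outdir, "variants"):
        pol = variants_mod.polarize_table(ds.site_counts)
        pol = variants_mod.annotate_table(pol, ds.cds_models, ds.transcripts)
        pol["loose_pass"] = variants_mod.loose_filter(
            pol, cfg.loose_min_cov, cfg.max_derived_in_normal
        )
        pol["strict_pass"] = variants_mod.strict_filter(
            pol, panel, cfg.strict_min_cov, cfg.min_allele, cfg.max_derived_in_normal
        )
        classified = pol["status"] == "polarized"
        pol["optimality"] = ""
        pol.loc[classified, "optimality"] = [
            density_mod.classify_optimality(a, d)
            for a, d in zip(pol.loc[classified, "ancestral"], pol.loc[classified, "derived"])
        ]
        status_counts = pol["status"].value_counts().to_dict()
        merged_loose = variants_mod.merge_patients(pol[pol["loose_pass"]])
        merged_strict = variants_mod.merge_patients(pol[pol["strict_pass"]])
        spec_summary = (
            variants_mod.spectrum(pol) if (pol["status"] == "polarized").any() else None
        )
        write_tsv(pol.sort_values(["gene", "pos", "patient"]), outdir / "variants_annotated.tsv")
        write_tsv(merged_loose, outdir / "variants_merged_loose.tsv")
        write_tsv(merged_strict, outdir / "variants_merged_strict.tsv")
        if spec_summary is not None:
            write_tsv(spec_summary.as_frame().reset_index(), outdir / "spectrum.tsv")
        n_rows = len(pol)
        report["stages"]["variants"] = {
            "n_rows": n_rows,
            "status_counts": {k: int(v) for k, v in sorted(status_counts.items())},
            "n_loose_rows": int(pol["loose_pass"].sum()),
            "n_strict_rows": int(pol["strict_pass"].sum()),
            "n_loose_sites": int(len(merged_loose)),
            "n_strict_sites": int(len(merged_strict)),
            "transition_fraction": (
                float(spec_summary.transition_fraction) if spec_summary else None
            ),
            # every input row is accounted for by its polarization status
            "accounting_ok": bool(sum(status_counts.values()) == n_rows),
        }

    with _stage(report, outdir, "offsets"):
        model = PsiteOffsetModel(
            window=cfg.window,
            min_reads=cfg.min_reads,
            min_peak_ratio=cfg.min_peak_ratio,
            min_frame_conc=cfg.min_frame_conc,
        )
        try:
            model.fit(ds.rpf_reads, ds.cds_models)
            offsets_found = {str(k): int(v) for k, v in sorted(model.offsets_.items())}
        except ValueError as e:
            # calibration failure is a warning, not an abort: the A-site
            # count tables are pre-tabulated and do not depend on it
            offsets_found = {}
            report.setdefault("warnings", []).append(f"offsets: {e}")
        table = getattr(model, "table_", pd.DataFrame(columns=["length", "qc_pass"]))
        write_tsv(table, outdir / "offsets.tsv")
        flagged = table[~table["qc_pass"].astype(bool)]["length"].tolist() if len(table) else []
        report["stages"]["offsets"] = {
            "offsets": offsets_found,
            "qc_flagged_lengths": [int(x) for x in flagged],
        }

    with _stage(report, outdir, "densities"):
        eligible = pol[
            pol["strict_pass"]
            & (pol["consequence"] == "synonymous")
            & pol["optimality"].isin(("optimal", "non_optimal"))
        ]
        records = density_mod.allele_densities(eligible)
        write_tsv(records, outdir / "allele_densities.tsv")
        comp_frames = []
        comparisons = {}
        for klass in ("optimal", "non_optimal"):
            n_class = int((records["optimality"] == klass).sum())
            if n_class >= cfg.min_sites:
                cr = density_mod.compare_groups(
                    records, klass, min_sites=cfg.min_sites, log2=cfg.log2_density
                )
                f = cr.as_frame()
                f.insert(0, "optimality", klass)
                comp_frames.append(f)
                comparisons[klass] = {
                    "n_sites": cr.n_sites,
                    "paired_t": cr.paired_t,
                    "paired_p": cr.paired_p,
                    "mean_tumor_ancestral": cr.mean_tumor_ancestral,
                    "mean_tumor_derived": cr.mean_tumor_derived,
                    "frac_ancestral_higher": cr.frac_ancestral_higher,
                }
            else:
                comparisons[klass] = {"n_sites": n_class, "skipped": "below min_sites"}
        if comp_frames:
            write_tsv(pd.concat(comp_frames, ignore_index=True), outdir / "density_comparisons.tsv")
        report["stages"]["densities"] = {
            "n_records": int(len(records)),
            "comparisons": comparisons,
        }

    with _stage(report, outdir, "gene_level"):
        gl: dict = {}
        summaries_by_tier = {}
        for tier, merged in (("loose", merged_loose), ("strict", merged_strict)):
            summ = genes_mod.gene_mutation_counts(merged, ds.cds_models)
            summ = summ.merge(ds.gene_classes, on="gene", how="left")
            summ["class"] = summ["class"].fillna("other")
            if len(ds.covariates):
                summ = summ.merge(ds.covariates, on="gene", how="left")
            if len(ds.gene_counts) and ds.library_sizes:
                gc = ds.gene_counts.set_index("gene").reindex(summ["gene"])
                lens = ds.cds_models.set_index("gene").reindex(summ["gene"])["transcript_len"]
                summ["te_normal"] = genes_mod.translation_efficiency(
                    gc["rna_normal"], gc["rpf_normal"], lens,
                    ds.library_sizes["rna_normal"], ds.library_sizes["rpf_normal"],
                )
                summ["te_tumor"] = genes_mod.translation_efficiency(
                    gc["rna_tumor"], gc["rpf_tumor"], lens,
                    ds.library_sizes["rna_tumor"], ds.library_sizes["rpf_tumor"],
                )
            summaries_by_tier[tier] = summ
            write_tsv(summ, outdir / f"gene_summaries_{tier}.tsv")
            tier_report: dict = {}
            try:
                enr = genes_mod.class_enrichment(summ)
                write_tsv(enr.as_frame(), outdir / f"enrichment_{tier}.tsv")
                tier_report["enrichment"] = enr.comparisons
            except ValueError as e:
                tier_report["enrichment"] = {"skipped": str(e)}
            if "te_normal" in summ.columns:
                predictors = [
                    p for p in genes_mod.DEFAULT_PREDICTORS if p in summ.columns
                ]
                try:
                    reg = genes_mod.te_regression(summ, predictors=tuple(predictors))
                    write_tsv(
                        reg.summary_frame().reset_index(),
                        outdir / f"te_regression_{tier}.tsv",
                    )
                    tier_report["regression"] = {
                        "coef": {k: float(v) for k, v in reg.coef_.items()},
                        "p_values": {k: float(v) for k, v in reg.pvalues_.items()},
                        "n_obs": reg.n_obs_,
                    }
                except ValueError as e:
                    tier_report["regression"] = {"skipped": str(e)}
            gl[tier] = tier_report
        report["stages"]["gene_level"] = gl

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# --------------------------------------------------------------------------
# Simulation-backed validation harness
# --------------------------------------------------------------------------

def simulate_and_validate(
    sim: SimConfig,
    outdir: str | Path,
    min_reads: int = 200,
) -> dict:
    """Generate synthetic data, run the pipeline, and compare every recovered
    quantity with the generator's ground truth.

    Returns ``{property: {"pass": bool, "detail": str}}``.  Null settings
    (speed factors at 1, enrichments at 1, zero TE effects) switch the
    corresponding directional checks to "null, as expected" mode.
    """
    ds = generate_dataset(sim)
    cfg = PipelineConfig(outdir=str(outdir), simulate=True, sim=sim,
                         min_reads=min_reads, seed=sim.seed)
    report = run_all(cfg, dataset=ds)
    results: dict[str, dict] = {}

    def check(name: str, ok: bool, detail: str) -> None:
        results[name] = {"pass": bool(ok), "detail": detail}

    # offsets recovered exactly for every programmed length
    got = {int(k): int(v) for k, v in report["stages"]["offsets"]["offsets"].items()}
    check(
        "offset_recovery",
        got == {int(k): int(v) for k, v in sim.offset_by_length.items()},
        f"inferred {got} vs programmed {sim.offset_by_length}",
    )

    # the strict-pass set contains only injected variants, none in the panel,
    # and its optimality calls match ground truth
    strict = read_tsv(Path(outdir) / "variants_merged_strict.tsv")
    truth = ds.truth_variants.set_index(["gene", "pos"])
    ok = True
    detail = f"{len(strict)} strict sites"
    for _, row in strict.iterrows():
        key = (row["gene"], row["pos"])
        if key not in truth.index:
            ok, detail = False, f"non-injected site {key} passed strict"
            break
        t = truth.loc[key]
        if bool(t["in_panel"]):
            ok, detail = False, f"panel site {key} passed strict"
            break
        if t["decoy"] == "" and row["optimality"] != t["optimality"]:
            ok, detail = False, f"optimality mismatch at {key}"
            break
    check("strict_set_and_optimality", ok, detail)

    # density direction per class
    comps = report["stages"]["densities"]["comparisons"]
    for klass, factor in (
        ("optimal", sim.speed_factor_optimal),
        ("non_optimal", sim.speed_factor_nonoptimal),
    ):
        c = comps.get(klass, {})
        if "skipped" in c:
            check(f"density_direction_{klass}", False, f"too few sites: {c}")
            continue
        if np.isclose(factor, 1.0):
            check(f"density_direction_{klass}", True, "null, as expected")
            continue
        expected_anc_higher = factor < 1.0
        observed = c["mean_tumor_ancestral"] > c["mean_tumor_derived"]
        check(
            f"density_direction_{klass}",
            observed == expected_anc_higher,
            f"anc={c['mean_tumor_ancestral']:.3f} der={c['mean_tumor_derived']:.3f}",
        )

    # enrichment directions on the loose tier
    enr = report["stages"]["gene_level"]["loose"].get("enrichment", {})
    if sim.enrich_opt_onco > 1.0 and "optimal_onco_vs_tsg" in enr:
        e = enr["optimal_onco_vs_tsg"]
        check(
            "enrichment_optimal_oncogene",
            e["direction"] == "oncogene>TSG" and e["p_value"] < 0.05,
            f"direction={e['direction']} p={e['p_value']:.2g}",
        )
    if sim.enrich_nonopt_tsg > 1.0 and "nonoptimal_onco_vs_tsg" in enr:
        e = enr["nonoptimal_onco_vs_tsg"]
        check(
            "enrichment_nonoptimal_tsg",
            e["direction"] == "TSG>oncogene" and e["p_value"] < 0.05,
            f"direction={e['direction']} p={e['p_value']:.2g}",
        )

    # regression signs on the loose tier
    reg = report["stages"]["gene_level"]["loose"].get("regression", {})
    if "coef" in reg and sim.te_effect_optimal != 0:
        ok = (
            reg["coef"]["n_optimal_syn"] > 0
            and reg["coef"]["n_nonoptimal_syn"] < 0
            and reg["p_values"]["n_optimal_syn"] < 0.01
            and reg["p_values"]["n_nonoptimal_syn"] < 0.01
        )
        check(
            "regression_signs",
            ok,
            f"beta_opt={reg['coef']['n_optimal_syn']:.3f} "
            f"beta_nonopt={reg['coef']['n_nonoptimal_syn']:.3f}",
        )

    check(
        "site_accounting",
        report["stages"]["variants"]["accounting_ok"],
        "all input rows carry a polarization status",
    )

    (Path(outdir) / "validation.json").write_text(
        json.dumps(results, indent=2, sort_keys=True)
    )
    return results


def run_fixture(outdir: str | Path) -> dict:
    """Run the full pipeline on the hand-specified worked fixture."""
    ds = worked_fixture()
    cfg = PipelineConfig(outdir=str(outdir), simulate=True, sim=ds.config,
                         min_reads=10, seed=0)
    return run_all(cfg, dataset=ds)


def config_to_yaml(cfg: PipelineConfig, path: str | Path) -> None:
    d = asdict(cfg)
    if d.get("sim"):
        d["sim"]["offset_by_length"] = {
            int(k): int(v) for k, v in d["sim"]["offset_by_length"].items()
        }
    d["window"] = list(d["window"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
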
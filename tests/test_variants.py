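"""Tests of polarization, the two filter tiers, consequence annotation,
spectrum summaries, and patient merging."""

import numpy as np
import pandas as pd
import pytest

from synoribo.io import COUNT_COLUMNS
from synoribo.simulate import SimConfig, generate_dataset
from synoribo.variants import (
    annotate_table,
    loose_filter,
    merge_patients,
    polarize,
    polarize_table,
    spectrum,
    strict_filter,
)

from conftest import brute_force_strict


def make_site(ref="A", outgroup="A", patient="P01", **counts):
    """Site-count row; counts given as e.g. rna_tumor_G=5."""
    row = {"gene": "gX", "pos": 100, "ref": ref, "outgroup": outgroup,
           "patient": patient, **{c: 0 for c in COUNT_COLUMNS}}
    row.update(counts)
    return row


class TestPolarize:
    def test_ref_matches_outgroup_gives_polarized_with_derived(self):
        s = polarize(make_site(rna_tumor_A=7, rna_tumor_G=5, rna_normal_A=10))
        assert s["status"] == "polarized"
        assert s["ancestral"] == "A" and s["derived"] == "G"

    def test_ref_differs_from_outgroup_is_non_ancestral(self):
        s = polarize(make_site(ref="A", outgroup="G", rna_tumor_A=7, rna_tumor_G=5))
        assert s["status"] == "non_ancestral_ref"

    def test_three_observed_tumor_alleles_is_multiallelic(self):
        s = polarize(
            make_site(ref="C", outgroup="C", rna_tumor_C=5, rna_tumor_T=2, rna_tumor_A=1)
        )
        assert s["status"] == "multiallelic"

    def test_outgroup_n_is_missing_outgroup_not_exception(self):
        s = polarize(make_site(outgroup="N", rna_tumor_A=5, rna_tumor_G=3))
        assert s["status"] == "missing_outgroup"

    def test_no_nonref_allele_is_monomorphic(self):
        s = polarize(make_site(rna_tumor_A=9))
        assert s["status"] == "monomorphic"


class TestLooseFilter:
    def _check(self, expected, **counts):
        df = polarize_table(pd.DataFrame([make_site(**counts)]))
        assert loose_filter(df).iloc[0] == expected

    def test_passes_with_covered_normal_and_het_tumor(self):
        self._check(True, rna_normal_A=10, rna_tumor_A=7, rna_tumor_G=5)

    def test_fails_when_normal_coverage_below_five(self):
        self._check(False, rna_normal_A=4, rna_tumor_A=7, rna_tumor_G=5)

    def test_fails_at_hundred_percent_tumor_mutation_level(self):
        self._check(False, rna_normal_A=10, rna_tumor_G=12)

    def test_fails_when_derived_seen_in_normal(self):
        self._check(False, rna_normal_A=10, rna_normal_G=1,
                    rna_tumor_A=7, rna_tumor_G=5)


class TestStrictFilter:
    BASE = dict(
        rna_normal_A=25, rpf_normal_A=22,
        rna_tumor_A=30, rna_tumor_G=10,
        rpf_tumor_A=18, rpf_tumor_G=7,
    )

    def _check(self, expected, panel=frozenset(), **overrides):
        counts = {**self.BASE, **overrides}
        df = polarize_table(pd.DataFrame([make_site(**counts)]))
        assert strict_filter(df, set(panel)).iloc[0] == expected

    def test_passes_all_five_criteria(self):
        self._check(True)

    def test_fails_when_tumor_rpf_derived_below_three(self):
        self._check(False, rpf_tumor_G=2)

    def test_fails_when_site_in_panel(self):
        self._check(False, panel={("gX", 100)})

    def test_fails_when_normal_rpf_coverage_below_twenty(self):
        self._check(False, rpf_normal_A=15)

    def test_fails_when_derived_in_normal_asite(self):
        self._check(False, rpf_normal_G=1)


class TestFilterProperties:
    def test_strict_pass_implies_loose_pass(self, small_sim):
        v = polarize_table(small_sim.site_counts)
        panel = set(zip(small_sim.panel["gene"], small_sim.panel["pos"]))
        strict = strict_filter(v, panel)
        loose = loose_filter(v)
        assert (loose[strict]).all()

    def test_strict_filter_matches_brute_force_oracle(self, small_sim):
        v = polarize_table(small_sim.site_counts)
        panel = set(zip(small_sim.panel["gene"], small_sim.panel["pos"]))
        got = set(
            v.loc[strict_filter(v, panel), ["gene", "pos", "patient"]]
            .itertuples(index=False, name=None)
        )
        assert got == brute_force_strict(v, panel)

    def test_panel_members_never_pass_strict(self):
        ds = generate_dataset(
            SimConfig(n_genes=60, n_onco=8, n_tsg=8, n_patients=2,
                      panel_fraction=0.2, seed=21)
        )
        v = polarize_table(ds.site_counts)
        panel = set(zip(ds.panel["gene"], ds.panel["pos"]))
        assert len(panel) > 0
        passed = v[strict_filter(v, panel)]
        assert not set(zip(passed["gene"], passed["pos"])) & panel


class TestAnnotate:
    def _annotate_one(self, seq, cds_start, cds_end, pos, anc, der):
        df = pd.DataFrame([{**make_site(ref=anc, outgroup=anc),
                            "pos": pos, "status": "polarized",
                            "ancestral": anc, "derived": der}])
        cds = pd.DataFrame([
            {"gene": "gX", "transcript_len": len(seq),
             "cds_start": cds_start, "cds_end": cds_end}
        ])
        return annotate_table(df, cds, {"gX": seq}).iloc[0]

    def test_third_position_same_aa_is_synonymous(self):
        seq = "AAAA" + "ATG" + "TTT" + "TAA" + "AA"  # CDS at [4, 13)
        v = self._annotate_one(seq, 4, 13, 9, "T", "C")  # TTT -> TTC, Phe
        assert v["consequence"] == "synonymous"

    def test_third_position_changed_aa_is_missense(self):
        seq = "AAAA" + "ATG" + "TTT" + "TAA" + "AA"
        v = self._annotate_one(seq, 4, 13, 9, "T", "A")  # TTT -> TTA, Phe->Leu
        assert v["consequence"] == "missense"

    def test_stop_gain_is_nonsense(self):
        seq = "AAAA" + "ATG" + "TAT" + "TAA" + "AA"
        v = self._annotate_one(seq, 4, 13, 9, "T", "A")  # TAT -> TAA
        assert v["consequence"] == "nonsense"

    def test_position_before_cds_is_utr5(self):
        seq = "AAAAAAAAAA" + "ATGTTTTAA" + "AA"
        v = self._annotate_one(seq, 10, 19, 4, "A", "G")
        assert v["consequence"] == "utr5"

    def test_position_after_cds_is_utr3(self):
        seq = "AAAA" + "ATGTTTTAA" + "AAAA"
        v = self._annotate_one(seq, 4, 13, 14, "A", "G")
        assert v["consequence"] == "utr3"

    def test_malformed_cds_model_raises(self):
        df = pd.DataFrame([make_site()])
        df["status"], df["ancestral"], df["derived"] = "polarized", "A", "G"
        cds = pd.DataFrame([{"gene": "gX", "transcript_len": 20,
                             "cds_start": 4, "cds_end": 12}])  # length 8
        with pytest.raises(ValueError, match="divisible by 3"):
            annotate_table(df, cds, {"gX": "A" * 20})

    def test_every_polarized_coding_variant_gets_one_consequence(self, small_sim):
        v = polarize_table(small_sim.site_counts)
        v = annotate_table(v, small_sim.cds_models, small_sim.transcripts)
        pol = v[v["status"] == "polarized"]
        assert pol["consequence"].isin(
            ["synonymous", "missense", "nonsense", "utr5", "utr3", "noncoding"]
        ).all()


class TestSpectrum:
    def _variants(self, changes):
        rows = []
        for anc, der in changes:
            rows.append({"status": "polarized", "ancestral": anc, "derived": der})
        return pd.DataFrame(rows)

    def test_transition_fraction_three_quarters(self):
        s = spectrum(self._variants([("A", "G")] * 3 + [("A", "C")]))
        assert s.transition_fraction == pytest.approx(0.75)

    def test_uniform_changes_give_one_third_transitions(self):
        changes = [(a, d) for a in "ACGT" for d in "ACGT" if a != d]
        s = spectrum(self._variants(changes))
        assert s.transition_fraction == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self):
        s = spectrum(self._variants([("A", "G"), ("C", "T"), ("G", "C")]))
        assert s.change_fractions.sum() == pytest.approx(1.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="polarized"):
            spectrum(pd.DataFrame({"status": [], "ancestral": [], "derived": []}))

    def test_fixture_spectrum_matches_hand_count(self, fixture_ds):
        v = polarize_table(fixture_ds.site_counts)
        s = spectrum(v)
        # hand count over the six fixture variants: T>C, A>G, G>T, C>A, T>G, A>C
        assert s.change_counts["T>C"] == 1
        assert s.change_counts["A>G"] == 1
        assert s.change_counts["G>T"] == 1
        # transitions: T>C and A>G
        assert s.transition_fraction == pytest.approx(2 / 6)


class TestMergePatients:
    def _df(self, entries):
        rows = []
        for gene, pos, der, patient in entries:
            rows.append({**make_site(patient=patient), "gene": gene, "pos": pos,
                         "status": "polarized", "ancestral": "A", "derived": der})
        return pd.DataFrame(rows)

    def test_union_of_overlapping_sets(self):
        df = self._df([("g", 1, "G", "P01"), ("g", 2, "G", "P01"),
                       ("g", 2, "G", "P02"), ("g", 3, "G", "P02")])
        merged = merge_patients(df)
        assert len(merged) == 3
        assert merged.set_index("pos").loc[2, "patients"] == "P01,P02"

    def test_disjoint_sets_sum(self):
        entries = [("g", i, "G", "P01") for i in range(4)]
        entries += [("g", i, "G", "P02") for i in range(10, 15)]
        assert len(merge_patients(self._df(entries))) == 9

    def test_conflicting_derived_alleles_stay_separate(self):
        df = self._df([("g", 5, "G", "P01"), ("g", 5, "T", "P02")])
        merged = merge_patients(df)
        assert len(merged) == 2
        assert set(merged["derived"]) == {"G", "T"}
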
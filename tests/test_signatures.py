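import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from phenocopy.core_io import AnalysisConfig
from phenocopy.signatures import (
    RegulationCallPair,
    SignatureSet,
    classify_profiles,
    cluster_treatments,
    counter_therapeutic_count,
    off_target_member,
    off_target_signature,
    on_target_signature,
    sirna_signature,
)
from phenocopy.simdata import (
    SIRNA_CONTROL,
    CompoundSpec,
    SimConfig,
    expected_profiles,
    generate_study,
)

CALLS = ("up", "down", "none")


class TestOffTargetRule:
    def test_truth_table_matches_exhaustive_enumeration(self):
        """Membership iff both arms are called, any sign combination."""
        for tgf, wotgf in itertools.product(CALLS, CALLS):
            expected = tgf != "none" and wotgf != "none"
            assert off_target_member(tgf, wotgf) is expected

    def test_signature_direction_from_unstimulated_arm(self, config):
        pairs = [
            RegulationCallPair("G1", "up", "down", 0.08, 2.0),
            RegulationCallPair("G2", "up", "none", 0.08, 2.0),
            RegulationCallPair("G3", "down", "down", 2.0, 4.0),
        ]
        result = off_target_signature(pairs, "BI1", config)
        assert result.pooled.members == {"G1": "down", "G3": "down"}
        assert set(result.per_time) == {2.0, 4.0}
        assert result.per_time[2.0].members == {"G1": "down"}

    def test_gene_counted_once_across_conditions(self, config):
        pairs = [
            RegulationCallPair("G1", "up", "up", 0.08, 2.0),
            RegulationCallPair("G1", "up", "up", 2.0, 2.0),
        ]
        result = off_target_signature(pairs, "BI1", config)
        assert len(result.pooled) == 1 and len(result.per_time[2.0]) == 1


class TestOnTargetSignature:
    def test_planted_recovery_with_noise(self, noisy_study):
        study, truths = noisy_study
        config = AnalysisConfig(seed=7, permutations_B=499)
        sig = on_target_signature(study, study.compounds(), 2.0, config)
        truth_on = {t.gene_id for t in truths if t.klass == "pure_on_target"}
        tgf_genes = {t.gene_id for t in truths if t.tgf_lr != 0}
        sensitivity = len(sig.genes & truth_on) / len(truth_on)
        fdp = len(sig.genes - tgf_genes) / max(len(sig), 1)
        assert sensitivity >= 0.90
        assert fdp <= 0.10

    def test_pure_off_target_genes_fail_stimulation_filter(self, noiseless_study, config):
        study, truths = noiseless_study
        sig = on_target_signature(study, study.compounds(), 2.0, config)
        off_only = {t.gene_id for t in truths if t.klass == "pure_off_target"}
        assert not (sig.genes & off_only)

    def test_directions_follow_stimulation_response(self, noiseless_study, config):
        study, truths = noiseless_study
        sig = on_target_signature(study, study.compounds(), 2.0, config)
        by_id = {t.gene_id: t for t in truths}
        for gene, direction in sig.members.items():
            expected = "up" if by_id[gene].tgf_lr > 0 else "down"
            assert direction == expected

    def test_missing_dose_series_names_compound(self, tiny_study, config):
        with pytest.raises(ValueError, match="BI9"):
            on_target_signature(tiny_study, ["BI9"], 2.0, config)


class TestSiRNASignature:
    def test_active_only_genes_included(self, noiseless_study, config):
        study, truths = noiseless_study
        sig = sirna_signature(study, 2.0, config)
        tgf_genes = {t.gene_id for t in truths if t.tgf_lr != 0}
        assert sig.genes and sig.genes <= tgf_genes

    def test_gene_responding_to_control_sirna_excluded(self, noiseless_study, config):
        study, truths = noiseless_study
        target = sorted(t.gene_id for t in truths if t.klass == "pure_on_target")[0]
        row = study.gene_index()[target]
        doctored = study.values.copy()
        ctrl_cols = study.select(modulator="sirna", compound_id=SIRNA_CONTROL, time_h=2.0)
        doctored[row, ctrl_cols] += 3.0
        from phenocopy.core_io import ExpressionStudy

        tampered = ExpressionStudy(study.genes, study.samples, doctored)
        sig = sirna_signature(tampered, 2.0, config)
        clean = sirna_signature(study, 2.0, config)
        assert target in clean.genes
        assert target not in sig.genes

    def test_missing_arm_rejected(self, tiny_study, config):
        with pytest.raises(ValueError, match="siRNA"):
            sirna_signature(tiny_study, 2.0, config)


class TestProfileClassification:
    def test_noiseless_recovery_of_planted_classes(self, noiseless_study):
        study, truths = noiseless_study
        config = AnalysisConfig(seed=5, permutations_B=199)
        profiles = classify_profiles(study, 2.0, config)
        expected = expected_profiles(truths, study.compounds())
        agreement = (profiles == expected.loc[profiles.index, profiles.columns]).to_numpy()
        assert agreement.all()

    def test_every_cell_gets_exactly_one_label(self, noiseless_study):
        study, _ = noiseless_study
        config = AnalysisConfig(seed=5, permutations_B=199)
        profiles = classify_profiles(study, 2.0, config)
        from phenocopy.signatures import PROFILE_CLASSES

        assert profiles.isin(PROFILE_CLASSES).to_numpy().all()
        assert profiles.shape == (study.n_genes, len(study.compounds()))


class TestCounterTherapeutic:
    def _signature(self):
        return SignatureSet(
            "on", "on_target", 2.0, {"G1": "up", "G2": "up", "G3": "down"}
        )

    def test_same_direction_push_counted(self):
        calls = [pd.Series({"G1": "up", "G2": "down", "G3": "none"})]
        assert counter_therapeutic_count(self._signature(), calls) == 1

    def test_opposing_push_not_counted(self):
        calls = [pd.Series({"G1": "down", "G2": "down", "G3": "up"})]
        assert counter_therapeutic_count(self._signature(), calls) == 0

    def test_no_calls_gives_zero(self):
        calls = [pd.Series({"G1": "none", "G2": "none", "G3": "none"})]
        assert counter_therapeutic_count(self._signature(), calls) == 0

    def test_gene_counted_once_across_tables(self):
        calls = [
            pd.Series({"G1": "up", "G2": "none", "G3": "none"}),
            pd.Series({"G1": "up", "G2": "none", "G3": "down"}),
        ]
        assert counter_therapeutic_count(self._signature(), calls) == 2


class TestTreatmentClustering:
    def _profile(self, lrs, calls, genes=("G1", "G2")):
        return pd.DataFrame({"lr": lrs, "call": calls}, index=list(genes))

    def test_identical_profiles_merge_at_zero(self):
        p = self._profile([1.0, 2.0], ["up", "up"])
        result = cluster_treatments({"a": p, "b": p.copy()})
        assert result.linkage[0, 2] == pytest.approx(0.0)

    def test_manhattan_distance_arithmetic(self):
        a = self._profile([1.0, 2.0], ["up", "up"])
        b = self._profile([4.0, 6.0], ["up", "up"])
        result = cluster_treatments({"a": a, "b": b})
        assert result.linkage[0, 2] == pytest.approx(7.0)

    def test_feature_union_is_significant_genes_only(self):
        a = self._profile([1.0, 0.1], ["up", "none"])
        b = self._profile([0.2, 0.1], ["none", "none"])
        result = cluster_treatments({"a": a, "b": b})
        assert result.feature_genes == ["G1"]

    def test_all_insignificant_rejected(self):
        a = self._profile([0.1, 0.1], ["none", "none"])
        with pytest.raises(ValueError, match="significant"):
            cluster_treatments({"a": a, "b": a.copy()})

    def test_chemotype_structure_recovered(self):
        """Fully chemotype-shared off-target draws with equal potencies: the
        top split of the treatment dendrogram separates the two scaffolds."""
        compounds = [
            CompoundSpec(f"BI{i}", 0.05, "indolinone", 1.0) for i in range(1, 6)
        ] + [CompoundSpec(f"Ex{i}", 0.05, "pyridopyrimidinone", 1.0) for i in (1, 2)]
        sim = SimConfig(
            n_genes=400,
            seed=17,
            compounds=compounds,
            chemotype_share_prob=1.0,
            times_h=(2.0,),
        )
        study, _ = generate_study(sim)
        config = AnalysisConfig(seed=3)
        from phenocopy.signatures import arm_contrast

        profiles = {
            c: arm_contrast(study, c, 2.0, 2.0, stimulated=True, config=config)
            for c in study.compounds()
        }
        result = cluster_treatments(profiles)
        flat = hierarchy.fcluster(result.linkage, t=2, criterion="maxclust")
        groups = {}
        for label, cl in zip(result.labels, flat):
            groups.setdefault(cl, set()).add(label)
        assert set(frozenset(g) for g in groups.values()) == {
            frozenset({"BI1", "BI2", "BI3", "BI4", "BI5"}),
            frozenset({"Ex1", "Ex2"}),
        }

    def test_newick_serialization_parses(self):
        a = self._profile([1.0, 2.0], ["up", "up"])
        b = self._profile([4.0, 6.0], ["up", "up"])
        c = self._profile([1.5, 2.5], ["up", "up"])
        result = cluster_treatments({"a": a, "b": b, "c": c})
        assert result.newick.endswith(";")
        assert {"a", "b", "c"} <= set(
            result.newick.replace("(", " ").replace(")", " ").replace(",", " ").split(":")[0].split()
        ) or all(x in result.newick for x in ("a", "b", "c"))
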
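import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phosphonet.errors import ValidationError
from phosphonet.network import SignallingNetwork
from phosphonet.seeds import (
    AMINO_ACIDS,
    KinasePrediction,
    MotifModel,
    build_seed_set,
    load_pwms,
    motif_score,
    predict_kinases,
    proximity_score,
    retain_kinases,
    substrate_seeds,
)
from phosphonet.synthetic import SyntheticSpec, gen_motif_models, sample_context

from conftest import make_summary


def uniform_model(kinase="K"):
    pwm = pd.DataFrame(
        np.full((11, 20), 0.05), index=range(-5, 6), columns=list(AMINO_ACIDS)
    )
    return MotifModel(kinase_id=kinase, pwm=pwm)


class TestSubstrateSeeds:
    def test_ci_excluding_zero_included_without_magnitude_threshold(self):
        s = make_summary(0.25, sigma=0.03, n=3)  # CI ~ [0.19, 0.31], |mu| < 0.5
        assert s.ci_low > 0
        seeds = substrate_seeds([s], "C1")
        assert seeds.members == {"PROT"}
        assert seeds.provenance["PROT"] == "substrate"

    def test_single_replicate_excluded(self):
        s = make_summary(3.0, sigma=0.0, n=1)
        assert substrate_seeds([s], "C1").members == set()

    def test_other_comparison_ignored(self):
        s = make_summary(1.0, sigma=0.05, n=3, comparison_id="C3")
        assert substrate_seeds([s], "C1").members == set()

    def test_null_inclusion_matches_monte_carlo_miscoverage(self):
        # independent Monte-Carlo oracle for the CI-only criterion: the same
        # normal model, but evaluated with plain numpy arithmetic
        rng = np.random.default_rng(99)
        n_prot, n_rep, sd = 4000, 3, 0.2

        def one_round(rng):
            x = rng.normal(0.0, sd, size=(n_prot, n_rep))
            mu = x.mean(axis=1)
            sigma = x.std(axis=1, ddof=1)
            return np.abs(mu) > 1.96 * sigma

        oracle_frac = one_round(np.random.default_rng(1234)).mean()

        flags = one_round(rng)
        summaries = []
        rng2 = np.random.default_rng(99)
        x = rng2.normal(0.0, sd, size=(n_prot, n_rep))
        for i in range(n_prot):
            mu = float(x[i].mean())
            sigma = float(x[i].std(ddof=1))
            summaries.append(
                make_summary(
                    mu, sigma=sigma, n=n_rep, protein=f"P{i}", site_key=f"P{i}(S1)"
                )
            )
        frac = len(substrate_seeds(summaries, "C1").members) / n_prot
        assert frac == pytest.approx(flags.mean(), abs=1e-12)
        assert frac == pytest.approx(oracle_frac, abs=0.02)


class TestMotifScore:
    def test_background_model_gives_unity(self):
        assert motif_score("ACDEFSIKLMN", uniform_model()) == pytest.approx(1.0)

    def test_fully_padded_gives_unity(self):
        assert motif_score("_" * 11, uniform_model()) == pytest.approx(1.0)

    def test_consensus_hand_product(self):
        # concentrated model: probability 0.7 on one residue per position;
        # oracle is the literal hand product over the three non-pad positions
        model = gen_motif_models(SyntheticSpec(seed=2), kinase_ids=["K"])[0]
        consensus = {
            pos: model.pwm.loc[pos].idxmax() for pos in (-1, 0, 1)
        }
        context = "____" + consensus[-1] + consensus[0] + consensus[1] + "____"
        expected = (0.7 / 0.05) ** 3
        assert motif_score(context, model) == pytest.approx(expected, rel=1e-9)

    def test_bad_length(self):
        with pytest.raises(ValidationError):
            motif_score("SHORT", uniform_model())

    def test_bad_symbol(self):
        with pytest.raises(ValidationError):
            motif_score("ACDEF1IKLMN", uniform_model())


class TestProximityScore:
    @pytest.fixture
    def path_graph(self):
        g = nx.path_graph(["A", "B", "C", "D", "E", "F", "G", "H"])
        return SignallingNetwork(graph=g)

    def test_reference_distance_unity(self, path_graph):
        assert proximity_score("A", "C", path_graph) == pytest.approx(1.0)

    def test_distance_one(self, path_graph):
        assert proximity_score("A", "B", path_graph) == pytest.approx(math.e)

    def test_unmapped_kinase(self, path_graph):
        assert proximity_score("ZZZ", "A", path_graph) == pytest.approx(math.exp(-4.0))

    def test_distance_capped(self, path_graph):
        # A..H are 7 hops apart; capped at d_max=6
        assert proximity_score("A", "H", path_graph) == pytest.approx(math.exp(-4.0))

    def test_disconnected(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("X")
        net = SignallingNetwork(graph=g)
        assert proximity_score("X", "A", net) == pytest.approx(math.exp(-4.0))


def pred(kinase, lr, site="P1(S1)", substrate="P1"):
    return KinasePrediction(
        site_key=site, substrate=substrate, kinase_id=kinase, motif_lr=lr, proximity_lr=1.0
    )


class TestRetainKinases:
    def test_hand_median(self):
        preds = [pred("A", 0.2), pred("B", 1.0), pred("C", 5.0)]
        kept, kinases = retain_kinases(preds)
        assert kinases == {"B", "C"}
        assert {p.kinase_id for p in kept} == {"B", "C"}

    def test_single_prediction_kept(self):
        kept, kinases = retain_kinases([pred("A", 0.001)])
        assert kinases == {"A"}

    def test_empty(self):
        kept, kinases = retain_kinases([])
        assert kept == [] and kinases == set()

    def test_at_least_half_survive(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            preds = [
                pred(f"K{i}", float(lr))
                for i, lr in enumerate(rng.lognormal(0, 1, int(rng.integers(1, 40))))
            ]
            kept, _ = retain_kinases(preds)
            assert len(kept) >= len(preds) / 2

    def test_both_provenance(self):
        seed_set = build_seed_set("C1", substrates={"AKT1", "X"}, kinases={"AKT1", "Y"})
        assert seed_set.provenance["AKT1"] == "both"
        assert seed_set.provenance["X"] == "substrate"
        assert seed_set.provenance["Y"] == "kinase"
        assert seed_set.substrates == {"AKT1", "X"}
        assert seed_set.kinases == {"AKT1", "Y"}


class TestCombinedLR:
    def test_log_additivity(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            m, x = rng.lognormal(0, 2, 2)
            p = KinasePrediction("s", "p", "k", float(m), float(x))
            assert math.log(p.combined_lr) == pytest.approx(
                math.log(m) + math.log(x), abs=1e-12
            )


class TestPlantedKinaseRecovery:
    def test_true_kinase_ranks_first(self):
        spec = SyntheticSpec(seed=21, n_kinases=4)
        models = gen_motif_models(spec, kinase_ids=["KTRUE", "KD1", "KD2", "KD3"])
        true_model = models[0]

        g = nx.Graph()
        substrates = [f"SUB{i}" for i in range(50)]
        for sub in substrates:
            g.add_edge("KTRUE", sub)
        # decoy kinases sit 4 hops from every substrate
        g.add_edge("KTRUE", "b1")
        g.add_edge("b1", "b2")
        g.add_edge("b2", "b3")
        for decoy in ("KD1", "KD2", "KD3"):
            g.add_edge("b3", decoy)
        net = SignallingNetwork(graph=g)

        rng = np.random.default_rng(77)
        site_contexts = {
            f"{sub}(S10)": (sub, sample_context(true_model, rng)) for sub in substrates
        }
        predictions = predict_kinases(site_contexts, models, net)
        by_site = {}
        for p in predictions:
            by_site.setdefault(p.site_key, []).append(p)
        wins = sum(
            1
            for preds in by_site.values()
            if max(preds, key=lambda p: p.combined_lr).kinase_id == "KTRUE"
        )
        assert wins / len(by_site) >= 0.90


class TestPwmIO:
    def test_round_trip(self, tmp_path):
        from phosphonet.synthetic import write_pwms

        models = gen_motif_models(SyntheticSpec(seed=3), kinase_ids=["KA", "KB"])
        path = tmp_path / "pwms.tsv"
        write_pwms(models, path)
        loaded = load_pwms(path)
        assert [m.kinase_id for m in loaded] == ["KA", "KB"]
        for orig, new in zip(models, loaded):
            pd.testing.assert_frame_equal(orig.pwm, new.pwm, check_exact=False)

    def test_rows_must_sum_to_one(self, tmp_path):
        models = gen_motif_models(SyntheticSpec(seed=3), kinase_ids=["KA"])
        models[0].pwm.iloc[0, 0] += 0.5
        from phosphonet.synthetic import write_pwms

        path = tmp_path / "pwms.tsv"
        write_pwms(models, path)
        with pytest.raises(ValidationError, match="sum to 1"):
            load_pwms(path)
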
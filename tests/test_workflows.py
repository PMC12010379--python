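import json

import numpy as np
import pandas as pd
import pytest

from autogs.genotype_io import GenotypeMatrix, write_phenotypes, write_vcf
from autogs.models.pool import ModelSpec
from autogs.simulate import (
    SimConfig,
    genetic_values,
    simulate_cross_population,
    simulate_genotypes,
    simulate_trait,
)
from autogs.training import ModelWeights, TrainOptions, train
from autogs.workflows import (
    RankedCrosses,
    StageError,
    make_f1_genotype,
    run_predict,
    run_select_parents,
    run_train,
    run_train_predict,
    run_train_select,
    select_parents,
)

FAST = TrainOptions(max_epochs=20, patience=8)


class TestMakeF1:
    def test_mendelian_cross(self):
        assert make_f1_genotype(np.array([0, 2, 0, 2]),
                                np.array([2, 2, 0, 0])).tolist() == [1, 2, 0, 1]

    def test_identical_parents(self):
        p = np.array([0, 2, 2, 0], dtype=np.int8)
        assert np.array_equal(make_f1_genotype(p, p), p)

    def test_heterozygous_parent_warns_but_applies_rule(self):
        with pytest.warns(UserWarning, match="heterozygous"):
            out = make_f1_genotype(np.array([1, 1]), np.array([0, 2]))
        assert out.tolist() == [0, 1]  # expected dosages 0.5 -> 0, 1.5 -> 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            make_f1_genotype(np.zeros(3), np.zeros(4))

    def test_600_crosses_match_lookup_table(self):
        sim = simulate_cross_population(20, 30,
                                        SimConfig(n=1, L=25, n_qtl=5, seed=20))
        table = {(0, 0): 0, (0, 2): 1, (2, 0): 1, (2, 2): 2}
        idx = {s: i for i, s in enumerate(sim.panel.samples)}
        for k, (f, m) in enumerate(sim.plan):
            pa, pb = sim.panel.dosage[idx[f]], sim.panel.dosage[idx[m]]
            expected = [table[(a, b)] for a, b in zip(pa.tolist(), pb.tolist())]
            assert sim.f1.dosage[k].tolist() == expected


def _linear_weights(sim):
    """A trained-weights stand-in whose predictions are the true linear model."""
    from autogs.models.classical import SkRegressor
    from sklearn.linear_model import LinearRegression

    reg = SkRegressor("RF")
    lr = LinearRegression()
    x = sim.f1.dosage.astype(float)
    g = genetic_values(sim.f1.dosage, sim.truth.beta, sim.truth.dom)
    lr.fit(x, g)
    reg.est = lr
    return ModelWeights(
        spec=ModelSpec(name="RF", seed=0),
        locus_map=list(sim.panel.loci),
        layout=(sim.panel.n_loci,),
        model_kind="classical",
        model_state=reg.get_state(),
    )


class TestSelectParents:
    @pytest.fixture(scope="class")
    def sim(self):
        return simulate_cross_population(
            10, 12, SimConfig(n=1, L=30, n_qtl=8, h2=0.9, seed=21)
        )

    def test_single_pair_is_rank_one(self, sim):
        w = _linear_weights(sim)
        out = select_parents(sim.panel, [sim.plan[0]], w)
        assert out.table["rank"].tolist() == [1]
        assert out.table["top5"].all()

    def test_rank_one_matches_bruteforce_argmax(self, sim):
        w = _linear_weights(sim)
        out = select_parents(sim.panel, sim.plan, w, "maximize")
        g = genetic_values(sim.f1.dosage, sim.truth.beta, sim.truth.dom)
        best = sim.plan[int(np.argmax(g))]
        top = out.table.iloc[0]
        assert (top["female"], top["male"]) == best

    def test_minimize_reverses_maximize(self):
        # needs a tie-free panel: with no equal predictions the minimize
        # ranking is the exact reverse of the maximize ranking
        sim = simulate_cross_population(
            10, 12, SimConfig(n=1, L=80, n_qtl=30, h2=0.9, seed=22)
        )
        w = _linear_weights(sim)
        up = select_parents(sim.panel, sim.plan, w, "maximize")
        assert up.table["predicted"].nunique() == len(up.table)  # no ties
        down = select_parents(sim.panel, sim.plan, w, "minimize")
        pairs_up = list(zip(up.table["female"], up.table["male"]))
        pairs_down = list(zip(down.table["female"], down.table["male"]))
        assert pairs_up == pairs_down[::-1]

    def test_ranking_invariant_under_relabeling(self, sim):
        w = _linear_weights(sim)
        base = select_parents(sim.panel, sim.plan, w)
        renamed = GenotypeMatrix(
            [f"x_{s}" for s in sim.panel.samples], sim.panel.loci, sim.panel.dosage
        )
        w2 = _linear_weights(sim)
        plan2 = [(f"x_{f}", f"x_{m}") for f, m in sim.plan]
        out2 = select_parents(renamed, plan2, w2)
        assert np.array_equal(out2.table["predicted"], base.table["predicted"])
        assert out2.table["rank"].tolist() == base.table["rank"].tolist()

    def test_unknown_parent_rejected(self, sim):
        w = _linear_weights(sim)
        with pytest.raises(ValueError, match="unknown parent"):
            select_parents(sim.panel, [("nope", sim.plan[0][1])], w)

    def test_supplied_f1_matrix_used(self, sim):
        w = _linear_weights(sim)
        built = select_parents(sim.panel, sim.plan, w)
        supplied = select_parents(sim.panel, sim.plan, w, f1=sim.f1)
        assert np.array_equal(built.table["predicted"], supplied.table["predicted"])

    def test_empty_plan_rejected(self, sim):
        with pytest.raises(ValueError, match="empty"):
            select_parents(sim.panel, [], _linear_weights(sim))


@pytest.fixture(scope="module")
def file_fixture(tmp_path_factory):
    root = tmp_path_factory.mktemp("wf")
    cfg = SimConfig(n=120, L=60, n_qtl=10, h2=0.9, seed=23)
    gm, vt = simulate_genotypes(cfg)
    pt, truth = simulate_trait(gm, cfg)
    write_vcf(root / "g.vcf", gm, vt)
    write_phenotypes(pt, root / "p.csv")
    return root, cfg, gm, pt


class TestRuns:
    def test_train_then_predict_self_consistency(self, file_fixture, tmp_path):
        root, cfg, gm, pt = file_fixture
        spec = ModelSpec(name="GBDT", seed=1, hyperparams={"n_estimators": 60})
        m = run_train(root / "g.vcf", root / "p.csv", tmp_path / "w.autogs", spec,
                      FAST, manifest_out=tmp_path / "m.json")
        assert (tmp_path / "w.autogs").exists()
        assert -1 <= m["r_test"] <= 1
        run_predict(root / "g.vcf", tmp_path / "w.autogs", tmp_path / "pred.csv")
        pred = pd.read_csv(tmp_path / "pred.csv", dtype={"sample": str})
        merged = pred.merge(pt.df, on="sample")
        from autogs.training import pearson_r

        assert pearson_r(merged["predicted"], merged["value"]) > 0.8  # mostly train data

    def test_train_predict_composition_byte_identical(self, file_fixture, tmp_path):
        root, *_ = file_fixture
        spec = ModelSpec(name="XGBoost", seed=2, hyperparams={"max_iter": 40})
        a = tmp_path / "a"
        b = tmp_path / "b"
        a.mkdir()
        b.mkdir()
        run_train(root / "g.vcf", root / "p.csv", a / "w.autogs", spec, FAST)
        run_predict(root / "g.vcf", a / "w.autogs", a / "pred.csv")
        run_train_predict(root / "g.vcf", root / "p.csv", b / "w.autogs",
                          b / "pred.csv", spec, FAST)
        assert (a / "w.autogs").read_bytes() == (b / "w.autogs").read_bytes()
        assert (a / "pred.csv").read_bytes() == (b / "pred.csv").read_bytes()

    def test_manifest_records_hashes(self, file_fixture, tmp_path):
        root, *_ = file_fixture
        spec = ModelSpec(name="RF", seed=3, hyperparams={"n_estimators": 20})
        m = run_train(root / "g.vcf", root / "p.csv", tmp_path / "w.autogs", spec,
                      FAST, manifest_out=tmp_path / "m.json")
        saved = json.loads((tmp_path / "m.json").read_text())
        assert saved["command"] == "train"
        assert set(saved["inputs"]) == {"vcf", "phenotypes"}
        assert len(saved["outputs"]["weights"]["sha256"]) == 64

    def test_envse_without_env_csv_errors(self, file_fixture, tmp_path):
        root, *_ = file_fixture
        with pytest.raises(StageError, match="environment"):
            run_train(root / "g.vcf", root / "p.csv", tmp_path / "w.autogs",
                      ModelSpec(name="EnvSE", seed=0), FAST)

    def test_stage_error_names_stage(self, tmp_path):
        (tmp_path / "bad.vcf").write_text("not a vcf")
        (tmp_path / "p.csv").write_text("sample,value\na,1.0\n")
        with pytest.raises(StageError, match=r"\[load-genotypes\]"):
            run_train(tmp_path / "bad.vcf", tmp_path / "p.csv",
                      tmp_path / "w.autogs", ModelSpec(name="RF", seed=0), FAST)

    def test_train_select_end_to_end(self, tmp_path):
        sim = simulate_cross_population(6, 8, SimConfig(n=1, L=40, n_qtl=8,
                                                        h2=0.9, seed=25))
        # train on the F1s themselves
        write_vcf(tmp_path / "f1.vcf", sim.f1,
                  _vt_for(sim.f1))
        write_phenotypes(sim.f1_phenotypes, tmp_path / "p.csv")
        write_vcf(tmp_path / "panel.vcf", sim.panel, _vt_for(sim.panel))
        pd.DataFrame(sim.plan, columns=["female", "male"]).to_csv(
            tmp_path / "pairs.csv", index=False
        )
        (tmp_path / "ids.txt").write_text("\n".join(sim.panel.samples) + "\n")
        run_train_select(
            tmp_path / "f1.vcf", tmp_path / "p.csv", tmp_path / "w.autogs",
            tmp_path / "panel.vcf", tmp_path / "ranked.csv", tmp_path / "top5.csv",
            ModelSpec(name="GBDT", seed=4, hyperparams={"n_estimators": 80}),
            FAST, pairs_path=tmp_path / "pairs.csv",
            inbred_list_path=tmp_path / "ids.txt", do_filter=False,
        )
        ranked = pd.read_csv(tmp_path / "ranked.csv")
        top5 = pd.read_csv(tmp_path / "top5.csv")
        assert len(ranked) == 48
        assert len(top5) == 5
        assert ranked["rank"].tolist() == list(range(1, 49))


def _vt_for(gm):
    import pandas as pd

    from autogs.genotype_io import INFO_METRICS, VariantTable

    rows = []
    for key in gm.loci:
        chrom, pos, ref, alt = key.split(":")
        rows.append({"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                     "qual": 50.0, **{m: np.nan for m in INFO_METRICS},
                     "missing_rate": 0.0})
    return VariantTable(pd.DataFrame(rows))
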
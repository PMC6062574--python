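import numpy as np
import pandas as pd
import pytest
from scipy import stats

from umisense.ercc import SpikeInDesign
from umisense.matrix import CountMatrix
from umisense.simdata import (
    MoleculeTable,
    SimConfig,
    amplify_and_sequence,
    capture_molecules,
    inject_crosstalk,
    inject_doublets,
    simulate_experiment,
    simulate_expression,
    spike_in_counts,
)


def _config(n_cells, means, disps, **kw):
    return SimConfig(
        n_cells=n_cells,
        gene_means=np.asarray(means, float),
        gene_dispersions=np.asarray(disps, float),
        **kw,
    )


class TestSimConfig:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            _config(4, [1.0, 2.0], [0.1])

    @pytest.mark.parametrize(
        "field,value",
        [
            ("capture_efficiency", 0.0),
            ("capture_efficiency", 1.5),
            ("doublet_rate", 0.5),
            ("crosstalk_rate", 0.25),
            ("pcr_cycles", -1),
            ("reads_per_cell", 0),
        ],
    )
    def test_bounds(self, field, value):
        with pytest.raises(ValueError):
            _config(4, [1.0], [0.0], **{field: value})

    def test_yaml_round_trip(self):
        cfg = _config(5, [1.0, 2.5], [0.0, 0.3], seed=42, crosstalk_rate=0.01)
        back = SimConfig.from_yaml(cfg.to_yaml())
        assert back == cfg

    def test_yaml_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_yaml("n_cells: 3\ngene_means: [1.0]\n"
                                "gene_dispersions: [0.0]\nbogus: 1\n")


class TestSimulateExpression:
    def test_poisson_moments(self):
        # phi = 0 degenerates to Poisson(5): mean and variance both 5
        cfg = _config(50_000, [5.0], [0.0], seed=11)
        x = simulate_expression(cfg).ravel().astype(float)
        se_mean = np.sqrt(5 / x.size)
        assert abs(x.mean() - 5) < 3 * se_mean
        # var of Poisson variance estimator: (mu + 2 mu^2)/n approx
        se_var = np.sqrt((5 + 2 * 25) / x.size)
        assert abs(x.var(ddof=1) - 5) < 3 * se_var

    def test_nb_variance(self):
        # var = mu + phi mu^2 = 5 + 0.5 * 25 = 17.5
        cfg = _config(50_000, [5.0], [0.5], seed=12)
        x = simulate_expression(cfg).ravel().astype(float)
        kurt = stats.kurtosis(x, fisher=True)
        se_var = np.sqrt((kurt + 2) / x.size) * x.var()
        assert abs(x.var(ddof=1) - 17.5) < 3 * se_var

    def test_empty_matrix(self):
        cfg = _config(0, [5.0, 1.0], [0.0, 0.0])
        assert simulate_expression(cfg).shape == (2, 0)

    def test_deterministic(self):
        cfg = _config(20, [2.0] * 10, [0.3] * 10, seed=5)
        assert np.array_equal(simulate_expression(cfg), simulate_expression(cfg))


class TestCapture:
    def test_identity_and_zero(self):
        x = np.arange(12).reshape(3, 4)
        assert np.array_equal(capture_molecules(x, 1.0, 0), x)
        assert capture_molecules(x, 0.0, 0).sum() == 0

    def test_p_out_of_range(self):
        with pytest.raises(ValueError):
            capture_molecules(np.ones((2, 2), int), 1.2)

    def test_detection_closed_form(self):
        # P(detect | m=5, p=0.1) = 1 - 0.9^5 = 0.40951
        rng = np.random.default_rng(3)
        x = np.full((1, 100_000), 5)
        detected = (capture_molecules(x, 0.1, rng) > 0).mean()
        expect = 1 - 0.9**5
        se = np.sqrt(expect * (1 - expect) / x.size)
        assert abs(detected - expect) < 3 * se

    @pytest.mark.parametrize("p", [0.05, 0.1, 0.5])
    @pytest.mark.parametrize("m", [1, 2, 4, 8, 16])
    def test_detection_curve_property(self, m, p):
        rng = np.random.default_rng(m * 100 + int(p * 1000))
        x = np.full((1, 40_000), m)
        detected = (capture_molecules(x, p, rng) > 0).mean()
        expect = 1 - (1 - p) ** m
        se = np.sqrt(max(expect * (1 - expect), 1e-9) / x.size)
        assert abs(detected - expect) < 4 * se


class TestSpikeInCounts:
    def test_zero_design(self):
        d = SpikeInDesign(["a"], np.array([0.0]))
        assert spike_in_counts(d, 0.5, 100, 0).sum() == 0

    def test_negative_design_rejected(self):
        with pytest.raises(ValueError):
            SpikeInDesign(["a"], np.array([-1.0]))

    def test_thinned_poisson_mean(self):
        d = SpikeInDesign(["a"], np.array([1000.0]))
        x = spike_in_counts(d, 0.5, 10_000, seed=2)
        se = np.sqrt(500 / x.size)  # thinned Poisson(500)
        assert abs(x.mean() - 500) < 3 * se

    def test_full_capture_is_poisson(self):
        d = SpikeInDesign(["a"], np.array([200.0]))
        x = spike_in_counts(d, 1.0, 20_000, seed=4).ravel()
        # randomized PIT makes discrete data uniform under H0, then KS applies
        rng = np.random.default_rng(99)
        dist = stats.poisson(200)
        u = dist.cdf(x - 1) + rng.random(x.size) * dist.pmf(x)
        pval = stats.kstest(u, "uniform").pvalue
        assert pval > 0.01

    def test_fixed_loading_integer_design(self):
        d = SpikeInDesign(["a"], np.array([7.0]))
        x = spike_in_counts(d, 1.0, 500, seed=1, loading="fixed")
        assert np.all(x == 7)

    def test_unknown_loading(self):
        d = SpikeInDesign(["a"], np.array([1.0]))
        with pytest.raises(ValueError, match="loading"):
            spike_in_counts(d, 0.5, 10, 0, loading="exotic")


def _captured_cm(counts, barcodes=None):
    counts = np.asarray(counts)
    barcodes = barcodes or [f"c{j}" for j in range(counts.shape[1])]
    return CountMatrix(counts, [f"g{i}" for i in range(counts.shape[0])], barcodes)


class TestAmplifyAndSequence:
    def test_read_conservation(self, small_config):
        cm = _captured_cm(np.random.default_rng(0).poisson(3, (20, 5)) + 1)
        table, _ = amplify_and_sequence(cm, small_config, seed=1)
        per_cell = table.df.groupby("cell")["reads"].sum()
        assert (per_cell == small_config.reads_per_cell).all()

    def test_zero_cycles_equal_weights(self):
        cfg = _config(1, [1.0], [0.0], pcr_cycles=0, reads_per_cell=1000)
        cm = _captured_cm(np.full((10, 1), 3))
        _, weights = amplify_and_sequence(cm, cfg, seed=0)
        assert np.allclose(weights, 1.0)

    def test_symmetric_multinomial_when_efficiency_constant(self):
        # alpha -> inf limit: near-constant efficiency => symmetric multinomial
        cfg = _config(
            1, [1.0], [0.0], pcr_efficiency_alpha=5e5, pcr_efficiency_beta=5e5,
            pcr_cycles=10, reads_per_cell=40_000,
        )
        cm = _captured_cm(np.full((40, 1), 1))  # 40 molecules
        table, _ = amplify_and_sequence(cm, cfg, seed=3)
        reads = table.df["reads"].to_numpy()
        expected = np.full(40, 40_000 / 40)
        chi2 = ((reads - expected) ** 2 / expected).sum()
        assert stats.chi2(39).sf(chi2) > 0.01

    def test_empty_cell_warns_not_fails(self, small_config):
        cm = _captured_cm(np.array([[2, 0], [1, 0]]))
        with pytest.warns(UserWarning, match="zero captured"):
            table, _ = amplify_and_sequence(cm, small_config, seed=0)
        assert set(table.df["cell"]) == {"c0"}

    def test_cv_increases_with_efficiency_variance(self):
        # same mean efficiency 0.9, decreasing alpha+beta => more dispersion
        settings = [(90.0, 10.0), (9.0, 1.0), (2.25, 0.25)]
        cvs = []
        for a, b in settings:
            cfg = _config(
                1, [1.0], [0.0], pcr_efficiency_alpha=a, pcr_efficiency_beta=b,
                pcr_cycles=12, reads_per_cell=100_000,
            )
            vals = []
            for seed in range(10):
                cm = _captured_cm(np.full((200, 1), 1))
                table, _ = amplify_and_sequence(cm, cfg, seed=seed)
                r = table.df["reads"].to_numpy(float)
                vals.append(r.std() / r.mean())
            cvs.append(np.mean(vals))
        assert cvs[0] < cvs[1] < cvs[2]


def _toy_table():
    df = pd.DataFrame(
        {
            "cell": ["c0", "c0", "c1", "c1", "c2"],
            "feature": ["g1", "g2", "g1", "g3", "g2"],
            "umi": ["u1", "u2", "u3", "u4", "u5"],
            "reads": [3, 1, 2, 2, 4],
        }
    )
    return MoleculeTable(df)


class TestDoublets:
    def test_rate_zero_identity(self):
        t = _toy_table()
        out, flags, pairs = inject_doublets(t, 0.0, seed=1)
        assert out == t and pairs == [] and not any(flags.values())

    def test_rate_bound(self):
        with pytest.raises(ValueError):
            inject_doublets(_toy_table(), 0.5)

    def test_disjoint_merge_sums(self):
        t = _toy_table()
        out, flags, pairs = inject_doublets(
            t, 0.4, seed=0, barcodes=["c0", "c1", "c2"]
        )
        assert len(pairs) == 1
        keep, absorb = pairs[0]
        merged = out.df[out.df["cell"] == keep]
        orig = t.df[t.df["cell"].isin([keep, absorb])]
        assert len(merged) == len(orig)  # disjoint UMI ids: pure union
        assert merged["reads"].sum() == orig["reads"].sum()
        assert flags[keep] and absorb not in flags

    def test_exact_merge_count(self):
        rng = np.random.default_rng(0)
        n = 100
        df = pd.DataFrame(
            {
                "cell": [f"c{i:03d}" for i in range(n)],
                "feature": ["g0"] * n,
                "umi": [f"u{i}" for i in range(n)],
                "reads": np.ones(n, int),
            }
        )
        out, flags, pairs = inject_doublets(MoleculeTable(df), 0.1, seed=2)
        assert len(pairs) == 10
        assert len(flags) == 90
        assert out.df["cell"].nunique() == 90

    def test_umi_collision_keeps_max_reads(self):
        # every cell carries the same (feature, umi) key, so any merge collides
        reads = {"a": 1, "b": 2, "c": 3, "d": 4}
        df = pd.DataFrame(
            {
                "cell": list(reads),
                "feature": ["g1"] * 4,
                "umi": ["u1"] * 4,
                "reads": list(reads.values()),
            }
        )
        out, _, pairs = inject_doublets(
            MoleculeTable(df), 0.49, seed=0, barcodes=list(reads)
        )
        assert len(pairs) == 1 and len(out) == 3
        keep, absorb = pairs[0]
        merged_reads = int(out.df.loc[out.df["cell"] == keep, "reads"].iloc[0])
        assert merged_reads == max(reads[keep], reads[absorb])


class TestCrosstalk:
    def test_rate_zero_identity(self):
        t = _toy_table()
        out, n = inject_crosstalk(t, 0.0, seed=0)
        assert n == 0 and out == t

    def test_conservation_and_rate(self):
        n_mol = 100_000
        df = pd.DataFrame(
            {
                "cell": np.repeat([f"c{i}" for i in range(50)], n_mol // 50),
                "feature": ["g0"] * n_mol,
                "umi": [f"u{i}" for i in range(n_mol)],
                "reads": np.ones(n_mol, int),
            }
        )
        out, moved = inject_crosstalk(MoleculeTable(df), 0.01, seed=1)
        assert len(out) == n_mol  # conservation
        se = np.sqrt(n_mol * 0.01 * 0.99)
        assert abs(moved - 1000) < 3 * se

    def test_moved_molecules_change_cell_only(self):
        t = _toy_table()
        out, moved = inject_crosstalk(t, 0.2, seed=3)
        assert len(out) == len(t)
        assert sorted(out.df["umi"]) == sorted(t.df["umi"])


class TestSimulateExperiment:
    def test_matrix_table_consistency(self, small_bundle, small_config):
        assert small_bundle.umi_matrix.values.sum() == len(small_bundle.table)
        assert (
            small_bundle.read_matrix.values.sum()
            == small_config.n_cells * small_config.reads_per_cell
        )

    def test_captured_le_true_endogenous(self, small_bundle, small_config):
        n_genes = small_config.n_genes
        cap = small_bundle.truth.captured_molecules[:n_genes]
        true = small_bundle.truth.true_molecules[:n_genes]
        assert np.all(cap <= true)

    def test_determinism(self, small_config, ladder):
        a = simulate_experiment(small_config, ladder)
        b = simulate_experiment(small_config, ladder)
        assert a.table == b.table
        assert np.array_equal(a.umi_matrix.values, b.umi_matrix.values)
        assert np.array_equal(a.read_matrix.values, b.read_matrix.values)

    def test_doublets_reduce_barcodes(self, ladder):
        cfg = _config(
            20, [2.0] * 50, [0.2] * 50, capture_efficiency=0.2,
            reads_per_cell=2000, doublet_rate=0.2, seed=9,
        )
        bundle = simulate_experiment(cfg, ladder)
        assert bundle.umi_matrix.n_cells == 16  # 4 pairs merged
        assert sum(bundle.truth.doublet_flags.values()) == 4


class TestMoleculeTable:
    def test_duplicate_key_rejected(self):
        df = pd.DataFrame(
            {"cell": ["a", "a"], "feature": ["g", "g"], "umi": ["u", "u"],
             "reads": [1, 2]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            MoleculeTable(df)

    def test_zero_reads_rejected(self):
        df = pd.DataFrame(
            {"cell": ["a"], "feature": ["g"], "umi": ["u"], "reads": [0]}
        )
        with pytest.raises(ValueError, match="reads"):
            MoleculeTable(df)
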
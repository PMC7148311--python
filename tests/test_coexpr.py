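"""Normalization, network construction and module detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from bloomdyn import coexpr, synthdata
from bloomdyn.coexpr import ModuleParams


def frame(arr, prefix="t"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestCoverageFilter:
    def test_boundary_mean_exactly_ten_kept(self):
        counts = frame([[10, 10, 10], [9, 10, 10]])
        out = coexpr.filter_low_coverage(counts, 10)
        assert list(out.index) == ["t0"]

    def test_empty_matrix(self):
        out = coexpr.filter_low_coverage(frame(np.empty((0, 3))), 10)
        assert out.empty


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = frame([[10, 10], [20, 20], [5, 5]])
        f = coexpr.size_factors(counts)
        assert np.allclose(f, 1.0)

    def test_doubled_sample_scales_factor(self):
        base = np.array([[10.0, 20.0], [30.0, 60.0], [7.0, 14.0]])
        f = coexpr.size_factors(frame(base))
        assert f["s1"] / f["s0"] == pytest.approx(2.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(2)
        counts = frame(rng.integers(1, 500, (50, 5)))
        f = coexpr.size_factors(counts)
        # independent oracle: literal median-of-ratios loop
        arr = counts.to_numpy(dtype=float)
        geo = np.exp(np.log(arr).mean(axis=1))
        expected = [np.median(arr[:, j] / geo) for j in range(arr.shape[1])]
        assert np.allclose(f.to_numpy(), expected)

    def test_fallback_when_no_common_transcript(self, caplog):
        counts = frame([[10, 0], [0, 10]])
        f = coexpr.size_factors(counts)
        assert (f > 0).all()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


def nb_counts(mu, disp, rng, n_samples=50):
    mu = np.asarray(mu, dtype=float)
    n = 1.0 / disp
    p = n / (n + mu)
    return rng.negative_binomial(n, p[:, None], size=(len(mu), n_samples))


class TestVST:
    def test_monotone_in_counts(self):
        q = np.linspace(0, 1e5, 2000)
        v = coexpr.vst_closed_form(q, a0=1.5, a1=0.2)
        assert (np.diff(v) > 0).all()

    def test_log2_asymptote(self):
        # one doubling at high counts gains one unit
        gap = coexpr.vst_closed_form(2e6, 1.5, 0.2) - coexpr.vst_closed_form(1e6, 1.5, 0.2)
        assert gap == pytest.approx(1.0, abs=0.01)

    def test_variance_flattening_on_nb_simulation(self):
        # simulation oracle: across a 100-fold mean range at fixed trend, the
        # transformed sd range collapses while the raw sd range stays wide
        rng = np.random.default_rng(4)
        means = np.repeat([20.0, 200.0, 2000.0], 300)
        counts = nb_counts(means, 0.3, rng)
        expr = coexpr.vst(frame(counts))
        assert not expr.fallback_log2
        raw_sd = pd.DataFrame(counts).std(axis=1)
        v_sd = expr.values.std(axis=1)
        groups = pd.Series(means).groupby(means).groups
        raw_group_sd = [raw_sd[list(ix)].mean() for ix in groups.values()]
        v_group_sd = [v_sd.iloc[list(ix)].mean() for ix in groups.values()]
        assert max(raw_group_sd) / min(raw_group_sd) >= 5
        assert max(v_group_sd) / min(v_group_sd) <= 2

    def test_fallback_on_poisson_like_data(self):
        # underdispersed counts have no NB trend to fit
        rng = np.random.default_rng(1)
        counts = frame(rng.poisson(5.0, size=(10, 8)))
        expr = coexpr.vst(counts)
        assert expr.fallback_log2
        assert np.isfinite(expr.values.to_numpy()).all()


class TestBicor:
    def test_affine_relation_gives_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        assert coexpr.bicor(x, 2 * x + 3) == pytest.approx(1.0, abs=1e-9)

    def test_negated_gives_minus_one(self):
        x = np.arange(10.0)
        assert coexpr.bicor(x, -x) == pytest.approx(-1.0, abs=1e-9)

    def test_robust_to_gross_outlier(self):
        # robustness oracle: the bicor of contaminated data stays closer to
        # the clean Pearson than the contaminated Pearson does
        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        y = 0.8 * x + 0.6 * rng.normal(size=60)
        clean_r = stats.pearsonr(x, y)[0]
        xc, yc = x.copy(), y.copy()
        xc[0], yc[0] = 12.0, -12.0
        contaminated_r = stats.pearsonr(xc, yc)[0]
        b = coexpr.bicor(xc, yc)
        assert abs(b - clean_r) < abs(contaminated_r - clean_r)

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 5.0])  # MAD 0
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        expected = stats.pearsonr(x, y)[0]
        assert coexpr.bicor(x, y) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            coexpr.bicor(np.arange(5.0), np.arange(4.0))


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """O(n^3) double-loop topological overlap, the independent oracle."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for u in range(n):
        for v in range(n):
            if u == v:
                continue
            shared = sum(a[u, w] * a[w, v] for w in range(n) if w not in (u, v))
            tom[u, v] = (shared + a[u, v]) / (min(k[u], k[v]) + 1 - a[u, v])
    return tom


class TestAdjacencyTOM:
    def test_two_perfectly_correlated_transcripts(self):
        x = np.arange(6.0)
        expr = frame([x, 2 * x + 1])
        tom = coexpr.adjacency_tom(expr, ModuleParams(correlation="pearson"))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_orthogonal_profiles_give_zero_overlap(self):
        t = np.arange(8.0)
        expr = frame([np.cos(2 * np.pi * t / 8), np.sin(2 * np.pi * t / 8)])
        tom = coexpr.adjacency_tom(expr, ModuleParams(correlation="pearson"))
        assert tom.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_toys(self, seed):
        rng = np.random.default_rng(seed)
        expr = frame(rng.normal(size=(6, 12)))
        params = ModuleParams(correlation="pearson", soft_power=6)
        tom = coexpr.adjacency_tom(expr, params)
        a = np.abs(np.corrcoef(expr.to_numpy())) ** 6
        oracle = brute_force_tom(a)
        assert np.abs(tom.to_numpy() - oracle).max() < 1e-12

    def test_bounds_symmetry_diagonal(self):
        rng = np.random.default_rng(9)
        expr = frame(rng.normal(size=(20, 15)))
        tom = coexpr.adjacency_tom(expr).to_numpy()
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1).all()
        assert np.allclose(np.diag(tom), 1.0)

    def test_higher_power_weakens_adjacency(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=20)
        y = 0.7 * x + 0.7 * rng.normal(size=20)
        r = abs(stats.pearsonr(x, y)[0])
        assert r**8 < r**6  # |corr| < 1 so larger beta shrinks adjacency

    def test_block_size_guard(self):
        expr = frame(np.random.default_rng(0).normal(size=(11, 5)))
        with pytest.raises(ValueError, match="max_block_size"):
            coexpr.adjacency_tom(expr, ModuleParams(max_block_size=10))


def block_expression(rng, sizes, n_samples=30, within=0.95):
    """Planted block-correlated expression: one latent profile per block."""
    rows = []
    for size in sizes:
        latent = rng.normal(size=n_samples)
        lam = np.sqrt(within)
        for _ in range(size):
            rows.append(lam * latent + np.sqrt(1 - within) * rng.normal(size=n_samples))
    return frame(np.array(rows))


class TestDetectModules:
    def test_separable_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        expr = block_expression(rng, [40, 40])
        params = ModuleParams(min_module_size=10, correlation="pearson")
        tom = coexpr.adjacency_tom(expr, params)
        labels = coexpr.detect_modules(tom, params)
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, labels) == 1.0
        assert labels.nunique() == 2

    def test_pure_noise_yields_no_modules(self):
        # false-module rate < 5% over 20 seeds
        false_modules = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = frame(rng.normal(size=(100, 30)))
            params = ModuleParams(min_module_size=30, correlation="pearson")
            tom = coexpr.adjacency_tom(expr, params)
            labels = coexpr.detect_modules(tom, params)
            if (labels > 0).any():
                false_modules += 1
        assert false_modules == 0

    def test_min_size_above_n_unassigns_everything(self):
        rng = np.random.default_rng(1)
        expr = block_expression(rng, [20])
        params = ModuleParams(min_module_size=1000)
        tom = coexpr.adjacency_tom(expr, params)
        labels = coexpr.detect_modules(tom, params)
        assert (labels == 0).all()

    def test_asymmetric_tom_rejected(self):
        tom = pd.DataFrame([[1.0, 0.2], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            coexpr.detect_modules(tom, ModuleParams())


class TestEigengene:
    def test_identical_profiles_reproduce_profile(self):
        profile = np.sin(np.linspace(0, 3, 12))
        expr = frame(np.tile(profile, (5, 1)) + 0.001 * np.random.default_rng(0).normal(size=(5, 12)))
        eg = coexpr.eigengene(expr, expr.index)
        assert abs(np.corrcoef(eg, profile)[0, 1]) > 0.999
        assert np.corrcoef(eg, expr.mean(axis=0))[0, 1] > 0

    def test_orientation_restored_after_sign_flip(self):
        rng = np.random.default_rng(3)
        expr = frame(rng.normal(size=(8, 10)))
        eg = coexpr.eigengene(expr, expr.index)
        flipped = -expr
        eg_flipped = coexpr.eigengene(flipped, flipped.index)
        # orientation follows each matrix's own mean profile
        assert np.corrcoef(eg, expr.mean(axis=0))[0, 1] >= 0
        assert np.corrcoef(eg_flipped, flipped.mean(axis=0))[0, 1] >= 0

    def test_matches_pca_oracle(self):
        # independent oracle: leading eigenvector of the sample covariance
        rng = np.random.default_rng(5)
        expr = frame(rng.normal(size=(30, 10)))
        eg = coexpr.eigengene(expr, expr.index).to_numpy()
        Z = stats.zscore(expr.to_numpy(), axis=1, ddof=0)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        pc1 = evecs[:, -1]
        assert min(
            np.abs(eg - pc1).max(), np.abs(eg + pc1).max()
        ) < 1e-8
        assert np.linalg.norm(eg) == pytest.approx(1.0)

    def test_constant_transcripts_dropped(self):
        rng = np.random.default_rng(6)
        arr = rng.normal(size=(4, 8))
        arr[0] = 3.14
        expr = frame(arr)
        eg = coexpr.eigengene(expr, expr.index)
        assert np.isfinite(eg).all()

    def test_too_small_module_rejected(self):
        expr = frame(np.random.default_rng(0).normal(size=(3, 5)))
        with pytest.raises(ValueError):
            coexpr.eigengene(expr, expr.index[:1])


class TestMergeModules:
    def test_identical_eigengenes_merge(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=20)
        rows = [latent + 0.01 * rng.normal(size=20) for _ in range(10)]
        expr = frame(np.array(rows))
        labels = pd.Series([1] * 5 + [2] * 5, index=expr.index)
        merged = coexpr.merge_modules(expr, labels)
        assert merged.nunique() == 1

    def test_threshold_is_strict(self):
        # two modules engineered to eigengene correlation exactly at threshold
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        a, b = stats.zscore(a), stats.zscore(b)
        rho = 0.75
        c = rho * a + np.sqrt(1 - rho**2) * (b - np.dot(a, b) / len(a) * a) / np.std(
            b - np.dot(a, b) / len(a) * a
        )
        expr = frame(np.array([a] * 5 + [c] * 5))
        labels = pd.Series([1] * 5 + [2] * 5, index=expr.index)
        egs = coexpr.eigengenes_for_labels(expr, labels)
        r = np.corrcoef(egs.iloc[0], egs.iloc[1])[0, 1]
        merged = coexpr.merge_modules(expr, labels, merge_corr_threshold=abs(r))
        assert merged.nunique() == 2  # equality does not merge

    def test_chain_matches_exhaustive_oracle(self):
        # three modules with pairwise eigengene correlations ~(0.9, 0.9, 0.5):
        # exhaustive merging collapses the chain into a single module because
        # merging recomputes eigengenes after each step
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        n1 = stats.zscore(rng.normal(size=40))
        mk = lambda r, noise: r * stats.zscore(base) + np.sqrt(1 - r**2) * noise
        profiles = [stats.zscore(base), mk(0.9, n1), mk(0.62, n1)]
        rows, labels = [], []
        for m, p in enumerate(profiles, start=1):
            for _ in range(6):
                rows.append(p + 0.05 * rng.normal(size=40))
                labels.append(m)
        expr = frame(np.array(rows))
        labels = pd.Series(labels, index=expr.index)
        merged = coexpr.merge_modules(expr, labels, 0.75)

        # oracle: exhaustive greedy merge over all orders, recomputing
        # eigengenes from scratch at every step
        def exhaustive(label_sets):
            while True:
                mods = sorted(label_sets)
                best = None
                for i, a in enumerate(mods):
                    for b in mods[i + 1 :]:
                        ea = coexpr.eigengene(expr, pd.Index(label_sets[a]))
                        eb = coexpr.eigengene(expr, pd.Index(label_sets[b]))
                        r = np.corrcoef(ea, eb)[0, 1]
                        if r > 0.75 and (best is None or r > best[0]):
                            best = (r, a, b)
                if best is None:
                    return label_sets
                _, a, b = best
                label_sets[a] = label_sets[a] + label_sets[b]
                del label_sets[b]

        init = {
            m: list(labels.index[labels == m]) for m in (1, 2, 3)
        }
        final = exhaustive(init)
        assert merged[merged > 0].nunique() == len(final)

    def test_terminates_within_module_count(self, default_modules):
        _, mods = default_modules
        assert len(mods.module_ids) >= 1  # merge converged


class TestComposition:
    def test_single_species_single_module(self):
        labels = pd.Series([1, 1, 1], index=["a", "b", "c"])
        sp = pd.Series("spA", index=["a", "b", "c"])
        comp = coexpr.module_composition(labels, sp)
        assert comp.loc[comp["taxon"] == "spA", "proportion"].iloc[0] == 1.0

    def test_proportions_sum_to_one_per_species(self, default_bundle, default_modules):
        _, mods = default_modules
        comp = coexpr.module_composition(
            mods.labels,
            default_bundle.counts.transcript_species,
            default_bundle.taxonomy,
        )
        sums = comp[comp["level"] == "species"].groupby("taxon")["proportion"].sum()
        assert np.allclose(sums, 1.0)


class TestFullPipeline:
    def test_recovers_planted_modules(self, default_bundle, default_modules):
        _, mods = default_modules
        truth = default_bundle.truth.transcript_module_labels.reindex(mods.labels.index)
        assert adjusted_rand_score(truth, mods.labels) >= 0.8

    def test_stable_across_count_noise(self, synthetic_module_params):
        # same generative truth, fresh negative-binomial noise
        cfg = synthdata.SimulationConfig()
        runs = []
        for count_seed in (11, 12):
            b = synthdata.simulate_community(cfg, count_seed=count_seed)
            _, mods = coexpr.run_coexpression(b.counts, synthetic_module_params)
            runs.append(mods.labels)
        joint = pd.concat(runs, axis=1, join="inner")
        assert adjusted_rand_score(joint.iloc[:, 0], joint.iloc[:, 1]) >= 0.9
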
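"""GI scoring: additive expectation, quadratic fit, normalization, RIGER, hits."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import combiscreen as cs
from combiscreen.interaction import (
    HitCriteria,
    call_hits,
    expected_z_gene,
    fit_quadratic,
    normalize_gi,
    raw_gi,
    riger_p,
    validation_concordance,
)
from combiscreen.library import CONTROL


def _gene_series(d: dict) -> pd.Series:
    idx = pd.MultiIndex.from_tuples(sorted(d), names=["gene_a", "gene_b"])
    return pd.Series([d[k] for k in sorted(d)], index=idx)


def test_expected_z_gene_sums_singles():
    z = _gene_series({
        ("A", CONTROL): -1.0,
        ("B", CONTROL): -2.0,
        (CONTROL, CONTROL): 0.1,
        ("A", "B"): -5.0,
        ("A", "A"): -3.0,
    })
    exp = expected_z_gene(z)
    assert exp[("A", "B")] == pytest.approx(-3.0)
    assert exp[("A", "A")] == pytest.approx(-2.0)  # 2 × single-gene Z
    assert exp[(CONTROL, CONTROL)] == pytest.approx(0.2)  # 2 × Z(Con,Con)


def test_expected_z_sgrna_level(scored_screen):
    """sgRNA-pair expectation = sum of control-partner means for each guide."""
    pheno, gi, truth = scored_screen
    design = truth.design
    control_ids = [s.id for s in design.control_sgrnas]
    z = pheno.z_sym.dropna()
    pair = gi.sgrna.index[100]
    a, b = pair

    def single(g):
        vals = [
            z[cs.sgrna_pair_key(g, c)] for c in control_ids
            if cs.sgrna_pair_key(g, c) in z.index
        ]
        return np.mean(vals)

    assert gi.sgrna.loc[pair, "expected_z"] == pytest.approx(single(a) + single(b))


def test_fit_quadratic_exact_and_constant():
    x = np.linspace(-4, 4, 25)
    y = 1 + 2 * x + 0.1 * x * x
    fit = fit_quadratic(x, y)
    assert fit.coefficients == pytest.approx((1.0, 2.0, 0.1), abs=1e-10)
    assert np.allclose(y - fit.predict(x), 0.0, atol=1e-10)
    const = fit_quadratic(x, np.full_like(x, 3.5))
    assert const.coefficients == pytest.approx((3.5, 0.0, 0.0), abs=1e-10)


def test_fit_quadratic_matches_normal_equations_oracle():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 2, 10)
    y = rng.normal(0, 1, 10)
    fit = fit_quadratic(x, y)
    X = np.vander(x, 3, increasing=True)  # independent normal-equations solve
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.coefficients, beta, atol=1e-8)


def test_fit_quadratic_least_squares_identities():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 2, 200)
    y = 0.5 + x - 0.05 * x**2 + rng.normal(0, 0.3, 200)
    resid, fit = raw_gi(pd.Series(x), pd.Series(y))
    assert abs(resid.sum()) < 1e-8
    for basis in (np.ones_like(x), x, x**2):
        assert abs(resid @ basis) < 1e-6


def test_fit_quadratic_rank_deficient():
    with pytest.raises(cs.InputError, match="distinct"):
        fit_quadratic([1.0, 1.0, 2.0], [0.0, 0.1, 0.2])


def test_normalize_gi_homoscedastic_unit_scale():
    """For Normal(0, σ) residuals the neighbor SD estimates σ, so the
    normalized scores have SD ≈ 1."""
    rng = np.random.default_rng(21)
    n = 600
    raw = pd.Series(rng.normal(0, 0.37, n), index=[f"u{i:03d}" for i in range(n)])
    expected = pd.Series(rng.normal(0, 3, n), index=raw.index)
    norm = normalize_gi(raw, expected, k=100)
    assert norm.std() == pytest.approx(1.0, abs=0.15)


def test_normalize_gi_clamps_k_with_warning():
    raw = pd.Series(np.arange(12, dtype=float) - 6)
    expected = pd.Series(np.arange(12, dtype=float))
    with pytest.warns(UserWarning, match="clamping"):
        norm = normalize_gi(raw, expected, k=200)
    assert norm.notna().all()


def test_normalize_gi_zero_sd_errors():
    raw = pd.Series(np.ones(30))
    expected = pd.Series(np.arange(30, dtype=float))
    with pytest.raises(cs.DegenerateNullError):
        normalize_gi(raw, expected, k=10)


def test_shift_of_observed_leaves_norm_gi_unchanged():
    """A constant added to all observed Z is absorbed by the quadratic fit."""
    rng = np.random.default_rng(31)
    expected = pd.Series(rng.normal(0, 2, 300))
    observed = expected + rng.normal(0, 0.4, 300)
    r1, _ = raw_gi(expected, observed)
    r2, _ = raw_gi(expected, observed + 5.0)
    n1 = normalize_gi(r1, expected, k=50)
    n2 = normalize_gi(r2, expected, k=50)
    assert np.allclose(n1, n2, atol=1e-8)


def test_gene_gi_mean_of_members(scored_screen):
    _, gi, truth = scored_screen
    design = truth.design
    pair = ("GENE01", "GENE02")
    members = [
        k for k in gi.sgrna.index
        if cs.gene_pair_key(design.gene_of(k[0]), design.gene_of(k[1])) == pair
    ]
    expect = gi.sgrna.loc[members, "norm_gi"].mean()
    assert gi.gene.loc[pair, "gene_gi"] == pytest.approx(expect)


def test_planted_interactions_score_negative_gi(scored_screen):
    _, gi, truth = scored_screen
    planted = gi.gene.loc[truth.planted, "gene_gi"]
    assert (planted < 0).all()
    # non-interacting double-target pairs center near zero
    others = gi.gene.drop(index=truth.planted)
    others = others[
        (others.index.get_level_values(0) != CONTROL)
        & (others.index.get_level_values(1) != CONTROL)
    ]
    assert abs(others["gene_gi"].mean()) < 0.5


def test_same_gene_pairs_get_doubled_expectation(scored_screen):
    pheno, gi, _ = scored_screen
    singles = {
        a: v for (a, b), v in pheno.gene["z_gene"].items()
        if b == CONTROL and a != CONTROL
    }
    for g, zg in singles.items():
        if (g, g) in gi.gene.index:
            assert gi.gene.loc[(g, g), "expected_z"] == pytest.approx(2 * zg)


# ---------------------------------------------------------------------------
# RIGER


def _riger_oracle(scores: pd.Series, groups: pd.Series):
    """Independent full-enumeration oracle for the weighted-sum statistic."""
    n = len(scores)
    rank = scores.rank(method="first").to_numpy() / n

    def stat(rs):
        rs = sorted(rs)
        return 0.25 * rs[0] + 0.75 * rs[1] if len(rs) > 1 else rs[0]

    out = {}
    for g in pd.unique(groups):
        mem = np.where((groups == g).to_numpy())[0]
        obs = stat(rank[mem])
        null = [stat(c) for c in itertools.combinations(rank, len(mem))]
        out[g] = sum(1 for s in null if s <= obs + 1e-12) / len(null)
    return out


@pytest.mark.parametrize("n_units,sizes", [(4, [2, 2]), (6, [2, 2, 2]), (8, [2, 3, 3])])
def test_riger_exact_matches_enumeration_oracle(n_units, sizes):
    rng = np.random.default_rng(n_units)
    scores = pd.Series(rng.normal(0, 1, n_units), index=[f"u{i}" for i in range(n_units)])
    labels = [f"g{j}" for j, m in enumerate(sizes) for _ in range(m)]
    groups = pd.Series(labels, index=scores.index)
    res = riger_p(scores, groups, method="exact")
    oracle = _riger_oracle(scores, groups)
    for g, p in oracle.items():
        assert res.loc[res.index == g].iloc[0]["riger_p"] == pytest.approx(p)


def test_riger_most_negative_group_gets_minimal_p():
    scores = pd.Series(
        [-9.0, -8.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
        index=[f"u{i}" for i in range(8)],
    )
    groups = pd.Series(["hit"] * 2 + ["x"] * 3 + ["y"] * 3, index=scores.index)
    res = riger_p(scores, groups, method="exact")
    p_hit = float(res[res.index == "hit"]["riger_p"].iloc[0])
    assert p_hit == pytest.approx(1 / 28)  # 1 / C(8,2): only the best assignment ties


def test_riger_median_group_near_half():
    # group at the exact middle of the ranking
    scores = pd.Series(np.arange(8, dtype=float), index=[f"u{i}" for i in range(8)])
    groups = pd.Series(["m" if i in (3, 4) else f"o{i}" for i in range(8)], index=scores.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # singleton groups fall back, flagged
        res = riger_p(scores, groups, method="exact")
    p_m = float(res[res.index == "m"]["riger_p"].iloc[0])
    assert 0.3 < p_m < 0.7


def test_riger_permutation_reproducible_and_bounded():
    rng = np.random.default_rng(55)
    scores = pd.Series(rng.normal(0, 1, 40), index=[f"u{i}" for i in range(40)])
    groups = pd.Series([f"g{i // 4}" for i in range(40)], index=scores.index)
    r1 = riger_p(scores, groups, n_perm=199, seed=3, method="permutation")
    r2 = riger_p(scores, groups, n_perm=199, seed=3, method="permutation")
    assert (r1["riger_p"] == r2["riger_p"]).all()
    assert ((r1["riger_p"] > 0) & (r1["riger_p"] <= 1)).all()
    with pytest.raises(cs.InputError, match="seed"):
        riger_p(scores, groups, n_perm=199, seed=None, method="permutation")
    with pytest.raises(cs.InputError, match="n_perm"):
        riger_p(scores, groups, n_perm=10, seed=3, method="permutation")


def test_riger_ks_statistic_ranks_planted_group_first():
    rng = np.random.default_rng(13)
    scores = pd.Series(rng.normal(0, 1, 30), index=[f"u{i}" for i in range(30)])
    scores.iloc[:3] = [-9.0, -8.5, -8.0]
    groups = pd.Series([f"g{i // 3}" for i in range(30)], index=scores.index)
    res = riger_p(scores, groups, n_perm=199, seed=1, method="permutation", statistic="ks")
    assert res["statistic"].idxmin() == "g0"


# ---------------------------------------------------------------------------
# hit calling and concordance


def test_call_hits_joint_cutoffs():
    idx = pd.MultiIndex.from_tuples(
        [("SRC", "YES1"), ("A", "B"), ("C", "D"), ("E", "F")],
        names=["gene_a", "gene_b"],
    )
    table = pd.DataFrame(
        {
            "gene_gi": [-3.95, -2.5, -1.0, -4.0],
            "riger_p": [0.001, 0.5, 0.001, 0.001],
            "observed_z": [-8.0, -6.0, -7.0, -3.0],
        },
        index=idx,
    )
    hits = call_hits(table, HitCriteria())
    assert list(hits.index) == [("SRC", "YES1")]  # others each fail one cutoff
    assert hits.iloc[0]["is_hit"]


def test_call_hits_sorted_by_gi():
    idx = pd.MultiIndex.from_tuples([("A", "B"), ("C", "D")], names=["gene_a", "gene_b"])
    table = pd.DataFrame(
        {"gene_gi": [-2.5, -6.0], "riger_p": [0.001, 0.001], "observed_z": [-6, -9]},
        index=idx,
    )
    assert list(call_hits(table).index) == [("C", "D"), ("A", "B")]


def test_validation_concordance():
    assert validation_concordance([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
    assert validation_concordance([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)
    # hand-computed Pearson r for a 4-point toy
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([1.0, 0.0, 3.0, 2.0])
    r_hand = ((x - x.mean()) @ (y - y.mean())) / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert validation_concordance(x, y) == pytest.approx(r_hand)
    with pytest.raises(cs.InputError):
        validation_concordance([1, 2], [1, 2])
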
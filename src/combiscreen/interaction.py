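"""Genetic-interaction (GI) scoring.

Under additivity, a double knockout's growth phenotype is predicted by the
sum of the two single-knockout phenotypes (each gene paired with control).
The observed-vs-expected Z cloud is summarized by a quadratic least-squares
trend; the raw GI score of a pair is its residual from that trend, and the
normalized GI divides the residual by the standard deviation of residuals
among the 200 nearest neighbors in expected Z (local heteroscedasticity).
Gene-level GI averages the member sgRNA pairs' normalized GIs; significance
comes from a rank-based permutation test (RIGER-style weighted-sum
statistic), and hits must clear GI, p, and observed-Z cutoffs jointly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateNullError, InputError
from .library import CONTROL, LibraryDesign, gene_pair_key
from .phenotype import PhenotypeTable


# ---------------------------------------------------------------------------
# expected Z under additivity


def expected_z_gene(z_gene: pd.Series) -> pd.Series:
    """Additive expectation per unordered gene pair: Z(A,Con) + Z(B,Con).

    ``z_gene`` is indexed by unordered gene-pair keys and must contain the
    single-with-control rows.  Same-gene pairs get 2×Z(A,Con); the
    control–control pair gets 2×Z(Con,Con).
    """
    singles: dict[str, float] = {}
    for (a, b), v in z_gene.items():
        if b == CONTROL and a != CONTROL:
            singles[a] = v
        elif a == CONTROL and b != CONTROL:
            singles[b] = v
        elif a == CONTROL and b == CONTROL:
            singles[CONTROL] = v
    vals = []
    for a, b in z_gene.index:
        za = singles.get(a)
        zb = singles.get(b)
        vals.append((za + zb) if (za is not None and zb is not None) else np.nan)
    return pd.Series(vals, index=z_gene.index).sort_index()


def expected_z_sgrna(z_sym: pd.Series, design: LibraryDesign) -> pd.Series:
    """Additive expectation per unordered sgRNA pair.

    The single-knockout phenotype of guide a is the mean of z_sym(a, con)
    over all control partners con; the expectation for (a, b) is the sum of
    the two guides' single phenotypes.
    """
    control_ids = {s.id for s in design.control_sgrnas}
    single_sum: dict[str, float] = {}
    single_n: dict[str, int] = {}
    for (a, b), v in z_sym.items():
        if np.isnan(v):
            continue
        if b in control_ids:
            single_sum[a] = single_sum.get(a, 0.0) + v
            single_n[a] = single_n.get(a, 0) + 1
        # unordered keys are sorted, so check both sides
        if a in control_ids and a != b:
            single_sum[b] = single_sum.get(b, 0.0) + v
            single_n[b] = single_n.get(b, 0) + 1
    single = {k: single_sum[k] / single_n[k] for k in single_sum}
    vals = []
    for a, b in z_sym.index:
        za = single.get(a)
        zb = single.get(b)
        vals.append((za + zb) if (za is not None and zb is not None) else np.nan)
    return pd.Series(vals, index=z_sym.index).sort_index()


# ---------------------------------------------------------------------------
# quadratic trend and residuals


@dataclass(frozen=True)
class QuadraticFit:
    """observed ≈ c0 + c1·expected + c2·expected², least squares."""

    c0: float
    c1: float
    c2: float
    domain: tuple[float, float]

    def predict(self, expected) -> np.ndarray:
        e = np.asarray(expected, dtype=float)
        return self.c0 + self.c1 * e + self.c2 * e * e

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.c0, self.c1, self.c2)


def fit_quadratic(expected, observed) -> QuadraticFit:
    """Ordinary least squares of observed on [1, expected, expected²]."""
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    ok = np.isfinite(e) & np.isfinite(o)
    e, o = e[ok], o[ok]
    if len(np.unique(e)) < 3:
        raise InputError("need >= 3 distinct expected values for a quadratic fit")
    c0, c1, c2 = np.polynomial.polynomial.polyfit(e, o, 2)
    return QuadraticFit(float(c0), float(c1), float(c2), (float(e.min()), float(e.max())))


def raw_gi(expected: pd.Series, observed: pd.Series, fit: QuadraticFit | None = None
           ) -> tuple[pd.Series, QuadraticFit]:
    """Residual of observed Z from the quadratic trend of expected Z."""
    if fit is None:
        fit = fit_quadratic(expected, observed)
    resid = observed - fit.predict(expected)
    return resid, fit


# ---------------------------------------------------------------------------
# nearest-neighbor normalization


def normalize_gi(
    raw: pd.Series,
    expected: pd.Series,
    k: int = 200,
) -> pd.Series:
    """Divide each raw GI by the SD of raw GIs among its k nearest
    neighbors in expected Z (self excluded; ties broken by unit id).

    If fewer than k other units exist, k shrinks to what is available
    (with a warning).
    """
    common = raw.index.intersection(expected.index)
    r = raw.loc[common].to_numpy(dtype=float)
    e = expected.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(r) & np.isfinite(e)
    idx = common[ok]
    r, e = r[ok], e[ok]
    n = len(r)
    if n < 2:
        raise InputError("need >= 2 units to normalize GI scores")
    if k > n - 1:
        warnings.warn(f"k={k} neighbors requested but only {n - 1} available; clamping",
                      stacklevel=2)
        k = n - 1
    if k < 2:
        raise InputError("need k >= 2 neighbors for an SD")

    # deterministic order: expected value, then unit id
    id_rank = np.argsort(np.argsort([str(t) for t in idx], kind="stable"))
    order = np.lexsort((id_rank, e))
    e_s = e[order]
    r_s = r[order]
    idr_s = id_rank[order]

    norm = np.empty(n)
    for pos in range(n):
        left = pos - 1
        right = pos + 1
        acc = 0.0
        acc2 = 0.0
        for _ in range(k):
            if left < 0:
                take_left = False
            elif right >= n:
                take_left = True
            else:
                dl = e_s[pos] - e_s[left]
                dr = e_s[right] - e_s[pos]
                if dl < dr:
                    take_left = True
                elif dr < dl:
                    take_left = False
                else:  # tie in distance: smaller unit id wins
                    take_left = idr_s[left] < idr_s[right]
            if take_left:
                v = r_s[left]
                left -= 1
            else:
                v = r_s[right]
                right += 1
            acc += v
            acc2 += v * v
        var = (acc2 - acc * acc / k) / (k - 1)
        sd = math.sqrt(var) if var > 0 else 0.0
        if sd <= 0:
            raise DegenerateNullError(
                "zero neighbor SD in GI normalization (constant residuals?)"
            )
        norm[pos] = r_s[pos] / sd

    out = np.empty(n)
    out[order] = norm
    return pd.Series(out, index=idx).reindex(raw.index)


# ---------------------------------------------------------------------------
# gene-level aggregation and permutation p-values


def gene_gi(norm_gi_sgrna: pd.Series, design: LibraryDesign) -> pd.DataFrame:
    """Mean normalized GI of the sgRNA pairs targeting each gene pair."""
    clean = norm_gi_sgrna.dropna()
    keys = [gene_pair_key(design.gene_of(a), design.gene_of(b)) for a, b in clean.index]
    grouped = clean.groupby(
        [
            pd.Index([k[0] for k in keys], name="gene_a"),
            pd.Index([k[1] for k in keys], name="gene_b"),
        ]
    )
    return pd.DataFrame(
        {"gene_gi": grouped.mean(), "n_sgrna_pairs": grouped.count()}
    ).sort_index()


def _weighted_sum_stat(norm_ranks_sorted: np.ndarray) -> float:
    """0.25×best + 0.75×second-best normalized rank (ascending scores)."""
    if len(norm_ranks_sorted) >= 2:
        return 0.25 * norm_ranks_sorted[0] + 0.75 * norm_ranks_sorted[1]
    return float(norm_ranks_sorted[0])


def _ks_stat(norm_ranks_sorted: np.ndarray) -> float:
    """Signed enrichment toward the top of the list (more negative = stronger)."""
    m = len(norm_ranks_sorted)
    j = np.arange(1, m + 1) / m
    return float(np.min(norm_ranks_sorted - j))


def riger_p(
    scores: pd.Series,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "auto",
    statistic: str = "weighted_sum",
    max_exact_n: int = 12,
) -> pd.DataFrame:
    """Rank-based gene-pair statistic with a permutation p-value.

    sgRNA-pair scores are ranked ascending (most negative first) and each
    gene pair is summarized by a weighted sum of its best two normalized
    ranks.  The null permutes the gene-pair→sgRNA-pair assignment; with
    ``method='exact'`` (automatic for small instances) all C(N, m) member
    sets are enumerated instead and p is the exact tail probability.
    Sampled p-values use the add-one correction (never zero).

    Returns a frame per gene pair: statistic, p, n_members, single_member.
    """
    if statistic not in ("weighted_sum", "ks"):
        raise InputError(f"unknown statistic {statistic!r}")
    scores = scores.dropna()
    groups = groups.reindex(scores.index)
    if groups.isna().any():
        raise InputError("every scored sgRNA pair needs a gene-pair group")
    n = len(scores)
    if n < 2:
        raise InputError("need >= 2 scored sgRNA pairs")

    stat_fn = _weighted_sum_stat if statistic == "weighted_sum" else _ks_stat

    # ranks ascending, ties broken by unit id for reproducibility
    id_rank = np.argsort(np.argsort([str(t) for t in scores.index], kind="stable"))
    order = np.lexsort((id_rank, scores.to_numpy(dtype=float)))
    rank = np.empty(n, dtype=float)
    rank[order] = np.arange(1, n + 1)
    norm_rank = rank / n

    group_keys = pd.unique(groups)
    members = {g: np.where((groups == g).to_numpy())[0] for g in group_keys}

    obs = {}
    single = {}
    for g, m_idx in members.items():
        r = np.sort(norm_rank[m_idx])
        obs[g] = stat_fn(r)
        single[g] = len(m_idx) < 2
        if single[g]:
            warnings.warn(
                f"gene pair {g} has a single sgRNA pair; using single-rank statistic",
                stacklevel=2,
            )

    if method == "auto":
        method = "exact" if n <= max_exact_n else "permutation"

    pvals = {}
    if method == "exact":
        all_ranks = np.arange(1, n + 1) / n
        sizes = sorted({len(m) for m in members.values()})
        null_by_size = {}
        for m in sizes:
            stats_m = np.array(
                [stat_fn(np.array(c)) for c in itertools.combinations(all_ranks, m)]
            )
            null_by_size[m] = np.sort(stats_m)
        for g, m_idx in members.items():
            null = null_by_size[len(m_idx)]
            pvals[g] = float(np.searchsorted(null, obs[g], side="right")) / len(null)
    elif method == "permutation":
        if n_perm < 99:
            raise InputError("n_perm must be >= 99")
        if seed is None:
            raise InputError("a seed is required for permutation p-values")
        rng = np.random.default_rng(seed)
        exceed = {g: 0 for g in group_keys}
        for _ in range(n_perm):
            perm = rng.permutation(norm_rank)
            for g, m_idx in members.items():
                if stat_fn(np.sort(perm[m_idx])) <= obs[g]:
                    exceed[g] += 1
        for g in group_keys:
            pvals[g] = (1 + exceed[g]) / (n_perm + 1)
    else:
        raise InputError(f"unknown method {method!r}")

    out = pd.DataFrame(
        {
            "statistic": pd.Series(obs),
            "riger_p": pd.Series(pvals),
            "n_members": pd.Series({g: len(m) for g, m in members.items()}),
            "single_member": pd.Series(single),
        }
    )
    if all(isinstance(g, tuple) and len(g) == 2 for g in out.index):
        out.index = pd.MultiIndex.from_tuples(out.index, names=["gene_a", "gene_b"])
    return out.sort_index()


# ---------------------------------------------------------------------------
# hit calling


@dataclass(frozen=True)
class HitCriteria:
    """Joint cutoffs for synthetic-lethal hit calling."""

    gi_cutoff: float = -2.0
    p_cutoff: float = 0.01
    z_cutoff: float = -5.0

    def __post_init__(self) -> None:
        for v in (self.gi_cutoff, self.p_cutoff, self.z_cutoff):
            if not np.isfinite(v):
                raise InputError("hit criteria must be finite")


def call_hits(gene_table: pd.DataFrame, criteria: HitCriteria | None = None) -> pd.DataFrame:
    """Flag gene pairs passing all three cutoffs; sorted by gene_gi ascending.

    Requires columns gene_gi, riger_p, observed_z.
    """
    crit = criteria or HitCriteria()
    for col in ("gene_gi", "riger_p", "observed_z"):
        if col not in gene_table.columns:
            raise InputError(f"gene table missing column {col!r}")
    hit = (
        (gene_table["gene_gi"] < crit.gi_cutoff)
        & (gene_table["riger_p"] < crit.p_cutoff)
        & (gene_table["observed_z"] < crit.z_cutoff)
    )
    out = gene_table.copy()
    out["is_hit"] = hit.fillna(False)
    return out[out["is_hit"]].sort_values("gene_gi")


def validation_concordance(screen_values, validation_values) -> float:
    """Pearson r between screen and validation values over matched gene pairs."""
    x = np.asarray(screen_values, dtype=float)
    y = np.asarray(validation_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InputError("need >= 3 matched gene pairs")
    return float(sps.pearsonr(x[ok], y[ok])[0])


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class InteractionConfig:
    """Knobs of GI scoring: neighbor count, permutations, hit cutoffs."""

    k_neighbors: int = 200
    n_perm: int = 999
    seed: int | None = None
    riger_statistic: str = "weighted_sum"
    riger_method: str = "auto"
    criteria: HitCriteria = field(default_factory=HitCriteria)


@dataclass
class GITable:
    """GI scores at both levels plus the fitted trends."""

    sgrna: pd.DataFrame  # expected_z, observed_z, raw_gi, norm_gi per sgRNA pair
    gene: pd.DataFrame  # expected_z, observed_z, raw_gi, norm_gi, gene_gi, riger_p, ...
    fit_sgrna: QuadraticFit
    fit_gene: QuadraticFit
    hits: pd.DataFrame


def score_interactions(
    pheno: PhenotypeTable,
    design: LibraryDesign,
    config: InteractionConfig | None = None,
) -> GITable:
    """Full GI scoring from a phenotype table.

    The quadratic fit and neighbor normalization run independently at the
    sgRNA-pair and gene-pair levels; the permutation test uses sgRNA-level
    normalized GIs grouped by gene pair.  The gene table reports both the
    direct gene-level normalized residual (``norm_gi``) and the mean of
    member sgRNA-pair normalized GIs (``gene_gi``); hit calling uses the
    latter.
    """
    cfg = config or InteractionConfig()

    # sgRNA-pair level
    obs_sg = pheno.z_sym.dropna()
    exp_sg = expected_z_sgrna(obs_sg, design)
    ok = exp_sg.notna() & obs_sg.reindex(exp_sg.index).notna()
    obs_sg = obs_sg.reindex(exp_sg.index)[ok]
    exp_sg = exp_sg[ok]
    raw_sg, fit_sg = raw_gi(exp_sg, obs_sg)
    norm_sg = normalize_gi(raw_sg, exp_sg, k=cfg.k_neighbors)
    sgrna_df = pd.DataFrame(
        {"expected_z": exp_sg, "observed_z": obs_sg, "raw_gi": raw_sg, "norm_gi": norm_sg}
    )

    # gene-pair level
    obs_g = pheno.gene["z_gene"]
    exp_g = expected_z_gene(obs_g)
    okg = exp_g.notna() & obs_g.reindex(exp_g.index).notna()
    obs_g = obs_g.reindex(exp_g.index)[okg]
    exp_g = exp_g[okg]
    raw_g, fit_g = raw_gi(exp_g, obs_g)
    norm_g = normalize_gi(raw_g, exp_g, k=cfg.k_neighbors)

    gg = gene_gi(norm_sg, design)
    groups = pd.Series(
        [gene_pair_key(design.gene_of(a), design.gene_of(b)) for a, b in norm_sg.index],
        index=norm_sg.index,
    )
    rp = riger_p(
        norm_sg,
        groups,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        method=cfg.riger_method,
        statistic=cfg.riger_statistic,
    )

    gene_df = pd.DataFrame(
        {
            "expected_z": exp_g,
            "observed_z": obs_g,
            "raw_gi": raw_g,
            "norm_gi": norm_g,
        }
    )
    gene_df = gene_df.join(gg, how="left").join(
        rp[["statistic", "riger_p"]], how="left"
    )
    hits = call_hits(gene_df.dropna(subset=["gene_gi", "riger_p"]), cfg.criteria)
    return GITable(sgrna=sgrna_df, gene=gene_df, fit_sgrna=fit_sg, fit_gene=fit_g, hits=hits)
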
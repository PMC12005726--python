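"""Ground-truth screen and synergy simulators.

The screen generator realizes the model the scoring pipeline assumes: each
ordered sgRNA pair (a, b) changes abundance over the screen by a log2 effect

    effect = e_a·f_g(a) + e_b·f_g(b) + e_a·e_b·i_{g(a),g(b)}

where f is per-gene fitness (controls 0), e ∈ [0,1] is per-guide cutting
efficiency, and i is the sparse pairwise-interaction matrix (planted
synthetic-lethal pairs are negative).  The interaction term is scaled by
both efficiencies: a pair only shows epistasis if both guides cut.  End
abundances are baseline × 2^(effect×timespan) plus per-replicate Gaussian
noise on the effect; sequencing counts are drawn negative-binomial
(gamma–Poisson) around the multinomial expectation at the configured depth.
All draws are deterministic functions of (config, seed).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import AnchorConfig, PairCountMatrix, pair_index, reverse_complement
from .errors import InputError
from .library import CONTROL, LibraryDesign, SgRNA, gene_pair_key
from .synergy import DoseMatrix

_BASES = np.array(list("ACGT"))


def make_design(
    n_genes: int = 12,
    n_sgrna_per_gene: int = 3,
    n_controls: int = 3,
    spacer_len: int = 20,
    seed: int = 0,
) -> LibraryDesign:
    """A synthetic library with random, unique spacers.

    Genes are named GENE01… and controls CTRL_sg1…; the default size
    (12 × 3 + 3 = 39 guides, 1,521 ordered pairs) keeps full-pipeline tests
    fast.  Use ``paper_scale_config`` for the 76 × 3 + 5 design.
    """
    rng = np.random.default_rng(seed)
    spacers: set[str] = set()
    sgrnas = []

    def draw_spacer() -> str:
        while True:
            s = "".join(rng.choice(_BASES, size=spacer_len))
            if s not in spacers:
                spacers.add(s)
                return s

    for g in range(n_genes):
        gene = f"GENE{g + 1:02d}"
        for j in range(n_sgrna_per_gene):
            sgrnas.append(SgRNA(id=f"{gene}_sg{j + 1}", spacer=draw_spacer(), gene=gene))
    for j in range(n_controls):
        sgrnas.append(SgRNA(id=f"CTRL_sg{j + 1}", spacer=draw_spacer(), gene=CONTROL))
    return LibraryDesign(sgrnas)


@dataclass
class SimConfig:
    """Study conditions of a simulated screen.

    Defaults describe a small but realistic pooled dropout screen: three
    guides per gene, three non-targeting controls, three biological
    replicates, a million reads per sample, moderate overdispersion
    (negative-binomial size 50), per-guide efficiencies ~Beta(8, 2), gene
    fitness ~Normal(0, 0.8) in log2 per screen, baseline library skew
    lognormal(σ=0.5), and per-pair replicate noise SD 0.7 — chosen so
    replicate-to-replicate phenotype correlations land near the ~0.75
    typical of real combinatorial screens.
    """

    n_genes: int = 12
    n_sgrna_per_gene: int = 3
    n_controls: int = 3
    n_replicates: int = 3
    depth: int = 1_000_000
    timespan: float = 1.0
    fitness_sd: float = 0.8
    gene_fitness: dict[str, float] | None = None
    interactions: dict[tuple[str, str], float] | None = None
    efficiency_beta: tuple[float, float] = (8.0, 2.0)
    replicate_noise_sd: float = 0.7
    baseline_sigma: float = 0.5
    nb_size: float = 50.0
    count_model: str = "nb"  # "nb" | "multinomial" | "expected"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count_model not in ("nb", "multinomial", "expected"):
            raise InputError("count_model must be 'nb', 'multinomial', or 'expected'")
        if self.replicate_noise_sd < 0 or self.baseline_sigma < 0:
            raise InputError("noise parameters must be >= 0")
        if self.nb_size <= 0:
            raise InputError("nb_size must be > 0")
        if self.seed is None:
            raise InputError("a seed is mandatory")


def paper_scale_config(seed: int = 0, **kwargs) -> SimConfig:
    """The 76-gene × 3-guide + 5-control screen scale (54,289 ordered pairs)."""
    kwargs.setdefault("depth", 20_000_000)
    return SimConfig(n_genes=76, n_sgrna_per_gene=3, n_controls=5, seed=seed, **kwargs)


@dataclass
class SimTruth:
    """Everything needed to check recovery against the generator."""

    pairs: pd.DataFrame  # per ordered pair: gene_a, gene_b, effect, interaction
    gene_fitness: pd.Series
    efficiency: pd.Series
    planted: list[tuple[str, str]]  # gene pairs with nonzero interaction
    config: SimConfig
    design: "LibraryDesign | None" = None

    def gene_pair_effect(self) -> pd.Series:
        """Mean noise-free pair effect per unordered gene pair."""
        keys = [gene_pair_key(a, b) for a, b in zip(self.pairs["gene_a"], self.pairs["gene_b"])]
        return self.pairs["effect"].groupby(
            pd.MultiIndex.from_tuples(keys, names=["gene_a", "gene_b"])
        ).mean()


def simulate_counts(
    cfg: SimConfig, design: LibraryDesign | None = None
) -> tuple[PairCountMatrix, SimTruth]:
    """Simulate a two-timepoint screen with replicates; returns counts + truth."""
    rng = np.random.default_rng(cfg.seed)
    if design is None:
        design = make_design(
            cfg.n_genes, cfg.n_sgrna_per_gene, cfg.n_controls,
            seed=int(rng.integers(2**31 - 1)),
        )
    ids = [s.id for s in design.sgrnas]
    genes = np.array([design.gene_of(i) for i in ids])
    n_sg = len(ids)

    eff = rng.beta(*cfg.efficiency_beta, size=n_sg)
    if cfg.gene_fitness is None:
        f_map = {g: rng.normal(0.0, cfg.fitness_sd) for g in design.genes}
    else:
        f_map = dict(cfg.gene_fitness)
    f_map[CONTROL] = 0.0
    f = np.array([f_map.get(g, 0.0) for g in genes])

    i_map: dict[tuple[str, str], float] = {}
    for (a, b), v in (cfg.interactions or {}).items():
        i_map[gene_pair_key(a, b)] = float(v)

    # ordered pair arrays (row-major over ids × ids)
    idx = pair_index(design)
    a_pos = np.repeat(np.arange(n_sg), n_sg)
    b_pos = np.tile(np.arange(n_sg), n_sg)
    ia = np.array(
        [i_map.get(gene_pair_key(genes[a], genes[b]), 0.0) for a, b in zip(a_pos, b_pos)]
    )
    effect = eff[a_pos] * f[a_pos] + eff[b_pos] * f[b_pos] + eff[a_pos] * eff[b_pos] * ia

    baseline = rng.lognormal(mean=0.0, sigma=cfg.baseline_sigma, size=len(effect))
    p0 = baseline / baseline.sum()

    def draw(p: np.ndarray) -> np.ndarray:
        mu = p * cfg.depth
        if cfg.count_model == "expected":
            return np.floor(mu + 0.5).astype(np.int64)
        if cfg.count_model == "multinomial":
            return rng.multinomial(cfg.depth, p).astype(np.int64)
        lam = rng.gamma(shape=cfg.nb_size, scale=mu / cfg.nb_size)
        return rng.poisson(lam).astype(np.int64)

    cols = {}
    meta = []
    for rep in range(1, cfg.n_replicates + 1):
        cols[f"D0_R{rep}"] = draw(p0)
        meta.append({"sample_id": f"D0_R{rep}", "timepoint": "D0", "replicate": rep})
    for rep in range(1, cfg.n_replicates + 1):
        noise = (
            rng.normal(0.0, cfg.replicate_noise_sd, size=len(effect))
            if cfg.replicate_noise_sd > 0
            else 0.0
        )
        w = p0 * np.exp2((effect + noise) * cfg.timespan)
        cols[f"D20_R{rep}"] = draw(w / w.sum())
        meta.append({"sample_id": f"D20_R{rep}", "timepoint": "D20", "replicate": rep})

    counts = pd.DataFrame(cols, index=idx)
    samples = pd.DataFrame(meta).set_index("sample_id")
    low = counts.sum(axis=0) < 2 * len(idx)
    if low.any():
        import warnings

        warnings.warn(
            f"sequencing depth below 2 reads/pair for samples {list(low[low].index)}",
            stacklevel=2,
        )

    truth = SimTruth(
        pairs=pd.DataFrame(
            {
                "gene_a": genes[a_pos],
                "gene_b": genes[b_pos],
                "effect": effect * cfg.timespan,
                "interaction": ia,
            },
            index=idx,
        ),
        gene_fitness=pd.Series(f_map),
        efficiency=pd.Series(eff, index=ids),
        planted=sorted({k for k, v in i_map.items() if v != 0.0}),
        config=cfg,
        design=design,
    )
    return PairCountMatrix(counts=counts, samples=samples), truth


# ---------------------------------------------------------------------------
# FASTQ emission


def simulate_fastq(
    counts: pd.Series,
    design: LibraryDesign,
    cfg: AnchorConfig,
    fastq_fwd: str | Path,
    fastq_rev: str | Path,
    read_len: int = 60,
    error_rate: float = 0.0,
    error_region: str = "all",
    seed: int = 0,
) -> int:
    """Emit one read pair per count unit; returns the number of read pairs.

    Forward reads are anchor+spacer1+random filler; reverse reads carry
    anchor+spacer2 and are reverse-complemented when the parser expects to
    undo that.  Substitution errors hit either the whole read or only the
    filler (``error_region``).  Gzipped output when the path ends in .gz.
    """
    if error_region not in ("all", "filler"):
        raise InputError("error_region must be 'all' or 'filler'")
    min_len = max(len(cfg.fwd_anchor), len(cfg.rev_anchor)) + cfg.spacer_len
    if read_len < min_len:
        raise InputError(f"read_len {read_len} too short for anchor+spacer ({min_len})")
    rng = np.random.default_rng(seed)
    spacer_of = {s.id: s.spacer for s in design.sgrnas}
    qual = "I" * read_len

    def mutate(seq: str, protected: int) -> str:
        if error_rate <= 0:
            return seq
        start = protected if error_region == "filler" else 0
        chars = list(seq)
        hits = np.nonzero(rng.random(read_len - start) < error_rate)[0] + start
        for h in hits:
            chars[h] = _BASES[(int(np.searchsorted(_BASES, chars[h])) + int(rng.integers(1, 4))) % 4]
        return "".join(chars)

    def open_out(path):
        path = Path(path)
        return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "wt")

    n_pairs = 0
    with open_out(fastq_fwd) as f1, open_out(fastq_rev) as f2:
        for (a, b), c in counts.items():
            c = int(c)
            if c <= 0:
                continue
            core_f = cfg.fwd_anchor + spacer_of[a]
            core_r = cfg.rev_anchor + spacer_of[b]
            for _ in range(c):
                n_pairs += 1
                filler_f = "".join(rng.choice(_BASES, size=read_len - len(core_f)))
                filler_r = "".join(rng.choice(_BASES, size=read_len - len(core_r)))
                fwd = mutate(core_f + filler_f, len(core_f))
                rev = mutate(core_r + filler_r, len(core_r))
                if cfg.rev_read_orientation == "reverse_complement":
                    rev = reverse_complement(rev)
                rid = f"sim_{n_pairs}"
                f1.write(f"@{rid}/1\n{fwd}\n+\n{qual}\n")
                f2.write(f"@{rid}/2\n{rev}\n+\n{qual}\n")
    return n_pairs


# ---------------------------------------------------------------------------
# dose-matrix simulation


@dataclass(frozen=True)
class HillCurve:
    """Four-parameter logistic viability curve (top fixed at 1, bottom 0)."""

    ec50: float
    slope: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.slope <= 0:
            raise InputError("Hill ec50 and slope must be positive")

    def viability(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            v = 1.0 / (1.0 + (d / self.ec50) ** self.slope)
        return np.where(d <= 0, 1.0, v)


def simulate_dose_matrix(
    doses_a,
    doses_b,
    hill_a: HillCurve,
    hill_b: HillCurve,
    interaction: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseMatrix:
    """Bliss-null product surface with an optional planted interaction.

    Combination cells (both doses > 0) are multiplied by 2^(−interaction),
    so interaction 0 is exactly Bliss-null and positive values produce
    positive mean Bliss excess.  Gaussian noise is added after, and the
    surface is clamped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    da = np.asarray(doses_a, dtype=float)
    db = np.asarray(doses_b, dtype=float)
    va = hill_a.viability(da)
    vb = hill_b.viability(db)
    v = va[:, None] * vb[None, :]
    interior = (da[:, None] > 0) & (db[None, :] > 0)
    v = np.where(interior, v * 2.0 ** (-interaction), v)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    v = np.clip(v, 0.0, 1.0)
    return DoseMatrix(da, db, v)


# ---------------------------------------------------------------------------
# recovery benchmark

#: Ten planted synthetic-lethal gene pairs used by the recovery benchmark.
PLANTED_PAIRS: list[tuple[str, str]] = [
    ("GENE01", "GENE02"), ("GENE03", "GENE04"), ("GENE05", "GENE06"),
    ("GENE07", "GENE08"), ("GENE09", "GENE10"), ("GENE11", "GENE12"),
    ("GENE01", "GENE03"), ("GENE02", "GENE04"), ("GENE05", "GENE07"),
    ("GENE06", "GENE08"),
]

#: Redundant-paralog analogue: two genes nearly neutral alone, strongly
#: synthetic lethal together (the classic SRC/YES-type redundancy).
PARALOG_PAIR: tuple[str, str] = ("GENE11", "GENE12")


def recovery_benchmark_config(seed: int, interaction: float = -2.0) -> SimConfig:
    """Default-noise 12-gene screen with ten planted interactions.

    Gene fitnesses are drawn Normal(0, 0.8) except the paralog pair, which
    is set near-neutral (−0.1 each) so its negative GI must come from the
    planted interaction, not from single-gene dropout.
    """
    rng = np.random.default_rng(seed)
    fitness = {f"GENE{i:02d}": float(rng.normal(0.0, 0.8)) for i in range(1, 11)}
    fitness[PARALOG_PAIR[0]] = -0.1
    fitness[PARALOG_PAIR[1]] = -0.1
    return SimConfig(
        seed=seed,
        gene_fitness=fitness,
        interactions={p: interaction for p in PLANTED_PAIRS},
    )


# ---------------------------------------------------------------------------
# recovery metrics


def planted_recovery_auroc(gene_table: pd.DataFrame, truth: SimTruth) -> float:
    """AUROC of gene_gi ranking for recovering planted interactions.

    Smaller (more negative) gene_gi should flag planted synthetic-lethal
    pairs; AUROC 1.0 means perfect separation.  Computed via the rank-sum
    statistic over double-target gene pairs.
    """
    from scipy.stats import mannwhitneyu

    gi = gene_table["gene_gi"].dropna()
    planted = set(truth.planted)
    labels = np.array([tuple(k) in planted for k in gi.index])
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise InputError("need both planted and non-planted gene pairs")
    pos = gi.to_numpy()[labels]
    neg = gi.to_numpy()[~labels]
    u = mannwhitneyu(neg, pos, alternative="greater").statistic
    return float(u / (len(pos) * len(neg)))
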
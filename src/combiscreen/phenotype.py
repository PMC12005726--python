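"""Growth-phenotype Z scores from pair counts.

The phenotype of an sgRNA pair is its normalized log2 fold change in
abundance between the screen end (D20) and start (D0).  Normalization
standardizes each replicate's fold changes against the control–control
pairs — the phenotypic null that exists by design in the library — using a
robust center/scale (median and 1.4826×MAD) by default.  Ordered
orientations (a,b)/(b,a) are averaged within replicate, then replicates are
averaged, then sgRNA pairs are averaged into gene-pair scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counting import PairCountMatrix, rpm_normalize
from .errors import DegenerateNullError, InputError
from .library import (
    CONTROL,
    LibraryDesign,
    gene_pair_key,
    sgrna_pair_key,
)


@dataclass
class PhenotypeConfig:
    """Tunable knobs of phenotype scoring.

    pseudocount: RPM added to both timepoints before the log ratio (default 1).
    min_d0_log10_rpm: pairs below this baseline abundance are excluded from
        scoring (fold changes off a near-zero baseline are noise).
    null_scale: "mad" (robust, default), "sd", or "unit" (center only; for
        noiseless data whose null has no spread).
    """

    pseudocount: float = 1.0
    min_d0_log10_rpm: float = 0.5
    null_scale: str = "mad"
    include_self_pairs: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise InputError("pseudocount must be > 0")
        if self.null_scale not in ("mad", "sd", "unit"):
            raise InputError("null_scale must be 'mad', 'sd', or 'unit'")


def log2_fold_change(d20_rpm, d0_rpm, pseudocount: float = 1.0):
    """log2((d20 + p) / (d0 + p)); symmetric zero when both are zero."""
    if pseudocount <= 0:
        raise InputError("pseudocount must be > 0")
    d20 = np.asarray(d20_rpm, dtype=float)
    d0 = np.asarray(d0_rpm, dtype=float)
    if (d20 < 0).any() or (d0 < 0).any():
        raise InputError("RPM values must be non-negative")
    out = np.log2((d20 + pseudocount) / (d0 + pseudocount))
    if np.isscalar(d20_rpm) and np.isscalar(d0_rpm):
        return float(out)
    return out


def z_score(
    lfc: pd.Series | np.ndarray,
    null_lfc: pd.Series | np.ndarray,
    method: str = "mad",
) -> tuple[pd.Series | np.ndarray, float, float]:
    """Standardize fold changes against a null class.

    z = (lfc - center(null)) / scale(null) with center = median and
    scale = 1.4826×MAD ("mad"), mean/SD ("sd"), or median/1 ("unit").
    Returns (z, center, scale).
    """
    null = np.asarray(null_lfc, dtype=float)
    null = null[np.isfinite(null)]
    if null.size < 5:
        raise InputError(f"need >= 5 null-class pairs, got {null.size}")
    if method == "sd":
        center = float(np.mean(null))
        scale = float(np.std(null, ddof=1))
    elif method == "unit":
        center = float(np.median(null))
        scale = 1.0
    elif method == "mad":
        center = float(np.median(null))
        scale = float(1.4826 * np.median(np.abs(null - center)))
    else:
        raise InputError(f"unknown z normalization {method!r}")
    if scale <= 0 or not np.isfinite(scale):
        raise DegenerateNullError(
            "null class has zero spread; cannot scale Z scores "
            "(consider null_scale='unit')"
        )
    return (lfc - center) / scale, center, scale


def combine_orientations(z_ordered: pd.Series) -> pd.Series:
    """Average the two orientations of each sgRNA pair.

    Input is indexed by ordered (sgrna_1, sgrna_2); output by the sorted
    unordered key.  A pair with one orientation missing passes through.
    """
    keys = [sgrna_pair_key(a, b) for a, b in z_ordered.index]
    sym = z_ordered.groupby(
        [
            pd.Index([k[0] for k in keys], name="sgrna_a"),
            pd.Index([k[1] for k in keys], name="sgrna_b"),
        ]
    ).mean()
    return sym.sort_index()


def aggregate_replicates(z_sym_by_rep: pd.DataFrame) -> pd.Series:
    """Mean z_sym across replicate columns (NaN-aware)."""
    if z_sym_by_rep.shape[1] < 1:
        raise InputError("need >= 1 replicate")
    return z_sym_by_rep.mean(axis=1)


def gene_level(z_sym: pd.Series, design: LibraryDesign) -> pd.DataFrame:
    """Average sgRNA-pair scores into unordered gene-pair scores.

    Returns a frame indexed by (gene_a, gene_b) with columns ``z_gene`` and
    ``n_sgrna_pairs`` (the number of scored member sgRNA pairs).
    """
    keys = [
        gene_pair_key(design.gene_of(a), design.gene_of(b)) for a, b in z_sym.index
    ]
    grouped = z_sym.groupby(
        [
            pd.Index([k[0] for k in keys], name="gene_a"),
            pd.Index([k[1] for k in keys], name="gene_b"),
        ]
    )
    out = pd.DataFrame({"z_gene": grouped.mean(), "n_sgrna_pairs": grouped.count()})
    return out.sort_index()


@dataclass
class PhenotypeTable:
    """All phenotype-scoring outputs for one screen."""

    ordered: pd.DataFrame  # per replicate: lfc, z, kept (long format)
    z_sym_by_rep: pd.DataFrame  # unordered sgRNA pair × replicate
    z_sym: pd.Series  # replicate-mean, unordered sgRNA pair
    gene: pd.DataFrame  # z_gene, n_sgrna_pairs per unordered gene pair
    null_stats: pd.DataFrame  # center/scale per replicate
    config: PhenotypeConfig = field(default_factory=PhenotypeConfig)


def _replicate_pairs(samples: pd.DataFrame) -> list[tuple[int, str, str]]:
    """Match D0 and D20 samples by replicate; a single D0 is broadcast."""
    d0 = samples[samples["timepoint"] == "D0"]
    d20 = samples[samples["timepoint"] == "D20"]
    if d0.empty or d20.empty:
        raise InputError("need both D0 and D20 samples")
    pairs = []
    for sid, row in d20.iterrows():
        rep = int(row["replicate"])
        match = d0[d0["replicate"].astype(int) == rep]
        if len(match) == 1:
            pairs.append((rep, match.index[0], sid))
        elif len(d0) == 1:
            pairs.append((rep, d0.index[0], sid))
        else:
            raise InputError(f"no unique D0 sample for replicate {rep}")
    return pairs


def score_phenotypes(
    counts: PairCountMatrix,
    design: LibraryDesign,
    config: PhenotypeConfig | None = None,
) -> PhenotypeTable:
    """Counts → per-replicate Z → orientation/replicate/gene aggregation."""
    cfg = config or PhenotypeConfig()
    rpm = rpm_normalize(counts.counts.astype(float))
    d0_floor = 10.0 ** cfg.min_d0_log10_rpm

    gene1 = np.array([design.gene_of(i) for i in counts.counts.index.get_level_values(0)])
    gene2 = np.array([design.gene_of(i) for i in counts.counts.index.get_level_values(1)])
    cc_mask = (gene1 == CONTROL) & (gene2 == CONTROL)
    if not cfg.include_self_pairs:
        self_mask = (
            counts.counts.index.get_level_values(0)
            == counts.counts.index.get_level_values(1)
        )
    else:
        self_mask = np.zeros(len(counts.counts), dtype=bool)

    ordered_rows = []
    sym_cols = {}
    null_rows = []
    for rep, s0, s20 in _replicate_pairs(counts.samples):
        r0 = rpm[s0]
        r20 = rpm[s20]
        kept = (r0.to_numpy() >= d0_floor) & ~self_mask
        lfc = pd.Series(
            log2_fold_change(r20.to_numpy(), r0.to_numpy(), cfg.pseudocount),
            index=rpm.index,
        )
        null_kept = cc_mask & kept
        z, center, scale = z_score(
            lfc[kept], lfc.to_numpy()[null_kept], cfg.null_scale
        )
        df = pd.DataFrame({"lfc": lfc, "kept": kept})
        df["z"] = z.reindex(df.index)
        df["replicate"] = rep
        ordered_rows.append(df)
        null_rows.append({"replicate": rep, "center": center, "scale": scale})
        sym_cols[rep] = combine_orientations(z)

    z_sym_by_rep = pd.DataFrame(sym_cols)
    z_sym = aggregate_replicates(z_sym_by_rep)
    gene = gene_level(z_sym.dropna(), design)
    return PhenotypeTable(
        ordered=pd.concat(ordered_rows),
        z_sym_by_rep=z_sym_by_rep,
        z_sym=z_sym,
        gene=gene,
        null_stats=pd.DataFrame(null_rows).set_index("replicate"),
        config=cfg,
    )


def qc_correlations(pheno: PhenotypeTable, grouping: str, design: LibraryDesign | None = None):
    """Pearson correlations between matched score vectors.

    grouping="orientation": r between z(a,b) and z(b,a) over ordered pairs
    (replicate-mean), one value.
    grouping="replicate": r for every replicate pair of z_sym, dict keyed by
    (rep_i, rep_j).
    grouping="sgrna_pairs_same_genes": r between same-rank member sgRNA
    pairs across gene pairs, dict keyed by (slot_i, slot_j); requires design.
    """
    if grouping == "orientation":
        z = (
            pheno.ordered.reset_index()
            .pivot_table(index=["sgrna_1", "sgrna_2"], columns="replicate", values="z")
            .mean(axis=1)
            .dropna()
        )
        ab, ba = [], []
        seen = set()
        for (a, b), v in z.items():
            if a >= b or (a, b) in seen:
                continue
            if (b, a) in z.index:
                seen.add((a, b))
                ab.append(v)
                ba.append(z[(b, a)])
        if len(ab) < 3:
            raise InputError("need >= 3 matched orientation pairs")
        return float(sps.pearsonr(ab, ba)[0])

    if grouping == "replicate":
        cols = list(pheno.z_sym_by_rep.columns)
        if len(cols) < 2:
            raise InputError("need >= 2 replicates")
        out = {}
        for i, ci in enumerate(cols):
            for cj in cols[i + 1 :]:
                sub = pheno.z_sym_by_rep[[ci, cj]].dropna()
                if len(sub) < 3:
                    raise InputError("need >= 3 matched observations")
                out[(ci, cj)] = float(sps.pearsonr(sub[ci], sub[cj])[0])
        return out

    if grouping == "sgrna_pairs_same_genes":
        if design is None:
            raise InputError("design required for same-gene-pair correlations")
        keys = [
            gene_pair_key(design.gene_of(a), design.gene_of(b))
            for a, b in pheno.z_sym.index
        ]
        df = pd.DataFrame({"z": pheno.z_sym.to_numpy(), "gene_pair": keys},
                          index=pheno.z_sym.index).dropna()
        df = df.sort_index()
        df["slot"] = df.groupby("gene_pair").cumcount()
        wide = df.pivot_table(index="gene_pair", columns="slot", values="z")
        out = {}
        for i in wide.columns:
            for j in wide.columns:
                if j <= i:
                    continue
                sub = wide[[i, j]].dropna()
                if len(sub) >= 3:
                    out[(int(i), int(j))] = float(sps.pearsonr(sub[i], sub[j])[0])
        if not out:
            raise InputError("not enough matched sgRNA-pair slots")
        return out

    raise InputError(f"unknown grouping {grouping!r}")
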
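"""Bliss-independence synergy models.

Bliss independence assumes two treatments act independently, so expected
combined inhibition is f_a + f_b − f_a·f_b — equivalently, survival
multiplies: s_ab = s_a·s_b.  The same law scores three validation
modalities: drug dose–response matrices (excess inhibition over the Bliss
surface), double-knockout fold changes (expected FC is the product of the
two single-knockout FCs), and xenograft tumor-volume trajectories (expected
relative volume is the product of the single-agent relative volumes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError


def bliss_expected_inhibition(f_a, f_b):
    """Expected combined inhibition under independence: f_a + f_b − f_a·f_b."""
    fa = np.asarray(f_a, dtype=float)
    fb = np.asarray(f_b, dtype=float)
    if ((fa < 0) | (fa > 1)).any() or ((fb < 0) | (fb > 1)).any():
        raise InputError("inhibition fractions must lie in [0, 1]")
    out = fa + fb - fa * fb
    if np.isscalar(f_a) and np.isscalar(f_b):
        return float(out)
    return out


@dataclass
class DoseMatrix:
    """Replicate-averaged viability over a dose grid (zero doses included).

    ``viability[i, j]`` is the surviving fraction at drug-A dose
    ``doses_a[i]`` and drug-B dose ``doses_b[j]``.  Values outside [0, 1]
    are clamped on construction (clamp events are warned about).
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (len(self.doses_a), len(self.doses_b)):
            raise InputError("viability shape must be (len(doses_a), len(doses_b))")
        for d, name in ((self.doses_a, "doses_a"), (self.doses_b, "doses_b")):
            if (np.diff(d) <= 0).any():
                raise InputError(f"{name} must be strictly increasing")
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise InputError("zero-dose margins are required (first dose must be 0)")
        n_clamped = int(((self.viability < 0) | (self.viability > 1)).sum())
        if n_clamped:
            warnings.warn(f"clamped {n_clamped} viability values into [0, 1]",
                          stacklevel=2)
            self.viability = np.clip(self.viability, 0.0, 1.0)

    @property
    def inhibition(self) -> np.ndarray:
        return 1.0 - self.viability


@dataclass
class BlissResult:
    """Per-cell Bliss excess plus the mean synergy score (percentage points)."""

    excess: np.ndarray  # observed − expected inhibition, full grid
    expected: np.ndarray
    mean_synergy_pct: float
    matrix: DoseMatrix


def bliss_excess_matrix(m: DoseMatrix) -> BlissResult:
    """Observed minus Bliss-expected inhibition per dose combination.

    Expectations come from the zero-dose margins; the summary score is the
    mean excess over cells where both doses are nonzero, ×100 (percentage
    points, matching common synergy-reporting conventions).
    """
    f = m.inhibition
    fa = f[:, 0]  # drug A alone (B dose 0)
    fb = f[0, :]  # drug B alone
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    excess = f - expected
    interior = (m.doses_a[:, None] > 0) & (m.doses_b[None, :] > 0)
    if not interior.any():
        raise InputError("dose matrix has no combination cells")
    mean_pct = float(100.0 * excess[interior].mean())
    return BlissResult(excess=excess, expected=expected, mean_synergy_pct=mean_pct, matrix=m)


def read_dose_matrix(path, drug_a: str = "drug_a", drug_b: str = "drug_b") -> DoseMatrix:
    """Read a wide CSV: first column = drug-A dose, header = drug-B doses."""
    df = pd.read_csv(path)
    doses_a = df.iloc[:, 0].to_numpy(dtype=float)
    try:
        doses_b = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise InputError(f"dose-matrix header must be numeric drug-B doses: {exc}") from None
    v = df.iloc[:, 1:].to_numpy(dtype=float)
    return DoseMatrix(doses_a, doses_b, v, drug_a=drug_a, drug_b=drug_b)


def write_bliss_report(result: BlissResult, path) -> None:
    """Long-format per-cell report: doses, observed/expected inhibition, excess."""
    m = result.matrix
    rows = []
    for i, da in enumerate(m.doses_a):
        for j, db in enumerate(m.doses_b):
            rows.append(
                {
                    "dose_a": da,
                    "dose_b": db,
                    "viability": m.viability[i, j],
                    "inhibition": m.inhibition[i, j],
                    "expected_inhibition": result.expected[i, j],
                    "bliss_excess": result.excess[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_bliss_heatmap(result: BlissResult, path) -> None:
    """Heat map of per-cell Bliss excess (red = synergy beyond independence)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = result.matrix
    fig, ax = plt.subplots(figsize=(5, 4))
    lim = max(0.05, float(np.abs(result.excess).max()))
    im = ax.imshow(result.excess, origin="lower", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(m.doses_b)), [f"{d:g}" for d in m.doses_b])
    ax.set_yticks(range(len(m.doses_a)), [f"{d:g}" for d in m.doses_a])
    ax.set_xlabel(f"{m.drug_b} dose")
    ax.set_ylabel(f"{m.drug_a} dose")
    ax.set_title(f"Bliss excess (mean {result.mean_synergy_pct:.1f} pp)")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# double-knockout fold-change validation


def expected_double_ko_fc(fc_a_con, fc_con_b):
    """Expected double-knockout fold change: FC(A+Con) × FC(Con+B)."""
    fa = np.asarray(fc_a_con, dtype=float)
    fb = np.asarray(fc_con_b, dtype=float)
    if (fa < 0).any() or (fb < 0).any():
        raise InputError("fold changes must be non-negative")
    out = fa * fb
    if np.isscalar(fc_a_con) and np.isscalar(fc_con_b):
        return float(out)
    return out


def knockout_synergy(
    fc_ab: float,
    fc_a_con: float,
    fc_con_b: float,
    fc_con_con: float = 1.0,
    tol: float = 0.05,
) -> dict:
    """Observed vs expected double-knockout fold change.

    Fold changes must be pre-normalized to the control–control combination
    (FC of sgCon+sgCon = 1 within ``tol``).  Synergy is observed − expected;
    negative values mean stronger-than-additive killing.
    """
    if abs(fc_con_con - 1.0) > tol:
        raise InputError(
            f"fold changes not normalized: FC(Con,Con) = {fc_con_con} != 1"
        )
    expected = expected_double_ko_fc(fc_a_con, fc_con_b)
    synergy = float(fc_ab - expected)
    return {
        "observed_fc": float(fc_ab),
        "expected_fc": float(expected),
        "synergy": synergy,
        "synergistic": synergy < 0,
    }


def knockout_validation_table(df: pd.DataFrame, tol: float = 0.05) -> pd.DataFrame:
    """Apply the product rule to a table of knockout validations.

    Needs columns fc_ab, fc_a_con, fc_con_b and optionally fc_con_con.
    """
    for col in ("fc_ab", "fc_a_con", "fc_con_b"):
        if col not in df.columns:
            raise InputError(f"knockout table missing column {col!r}")
    out = df.copy()
    con = out["fc_con_con"] if "fc_con_con" in out.columns else pd.Series(1.0, index=out.index)
    rows = [
        knockout_synergy(r.fc_ab, r.fc_a_con, r.fc_con_b, c, tol)
        for r, c in zip(df.itertuples(index=False), con)
    ]
    extra = pd.DataFrame(rows, index=df.index)
    out[["expected_fc", "synergy", "synergistic"]] = extra[
        ["expected_fc", "synergy", "synergistic"]
    ]
    return out


# ---------------------------------------------------------------------------
# tumor-volume trajectories


def tumor_volume(width, length):
    """Caliper volume: width² × length × 0.5 (mm³)."""
    w = np.asarray(width, dtype=float)
    ln = np.asarray(length, dtype=float)
    if (w < 0).any() or (ln < 0).any():
        raise InputError("width and length must be non-negative")
    out = w * w * ln * 0.5
    if np.isscalar(width) and np.isscalar(length):
        return float(out)
    return out


@dataclass
class TumorSeries:
    """Per-animal tumor volumes over time for the four treatment groups."""

    data: pd.DataFrame  # columns: group, day, volume (one row per animal)
    groups: tuple[str, str, str, str] = ("vehicle", "drug_a", "drug_b", "combo")

    def __post_init__(self) -> None:
        for col in ("group", "day", "volume"):
            if col not in self.data.columns:
                raise InputError(f"tumor series missing column {col!r}")
        if (self.data["volume"] < 0).any():
            raise InputError("tumor volumes must be non-negative")
        missing = set(self.groups) - set(self.data["group"])
        if missing:
            raise InputError(f"tumor series missing groups: {sorted(missing)}")


def bliss_expected_tumor(series: TumorSeries) -> pd.DataFrame:
    """Bliss additivity on relative tumor volumes, per timepoint.

    Expected combo relative volume = (V_A/V_veh) × (V_B/V_veh); excess =
    observed combo relative volume − expected (negative = synergistic
    shrinkage).  Group SDs propagate into the relative and expected values
    by first-order error propagation.
    """
    veh, ga, gb, combo = series.groups
    stats = (
        series.data.groupby(["group", "day"])["volume"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "m", "std": "s", "count": "n"})
    )
    days = sorted(series.data.loc[series.data["group"] == veh, "day"].unique())
    rows = []
    for day in days:
        try:
            mv, sv = stats.loc[(veh, day), ["m", "s"]]
            ma, sa = stats.loc[(ga, day), ["m", "s"]]
            mb, sb = stats.loc[(gb, day), ["m", "s"]]
            mc, sc = stats.loc[(combo, day), ["m", "s"]]
        except KeyError:
            raise InputError(f"groups do not share timepoint {day}") from None
        if mv <= 0:
            raise InputError(f"vehicle mean volume is zero at day {day}")
        sv = 0.0 if np.isnan(sv) else sv
        rel = {"a": ma / mv, "b": mb / mv, "combo": mc / mv}
        rel_err = {
            "a": rel["a"] * np.sqrt((sa / ma) ** 2 + (sv / mv) ** 2) if ma > 0 else np.nan,
            "b": rel["b"] * np.sqrt((sb / mb) ** 2 + (sv / mv) ** 2) if mb > 0 else np.nan,
            "combo": rel["combo"] * np.sqrt((sc / mc) ** 2 + (sv / mv) ** 2) if mc > 0 else np.nan,
        }
        expected = rel["a"] * rel["b"]
        exp_err = (
            expected
            * np.sqrt(
                (rel_err["a"] / rel["a"]) ** 2 + (rel_err["b"] / rel["b"]) ** 2
            )
            if rel["a"] > 0 and rel["b"] > 0
            else np.nan
        )
        rows.append(
            {
                "day": day,
                "rel_volume_a": rel["a"],
                "rel_volume_b": rel["b"],
                "rel_volume_combo": rel["combo"],
                "rel_volume_combo_sd": rel_err["combo"],
                "expected_rel_volume": expected,
                "expected_rel_volume_sd": exp_err,
                "bliss_excess": rel["combo"] - expected,
            }
        )
    return pd.DataFrame(rows).set_index("day")
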
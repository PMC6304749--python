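"""Firing-rate measurement pipeline.

Covers the downstream measurements applied to spike records and sweep
tables: network-mean spike frequency (MSF) with burn-in, percent modulation
with its predicted/unpredicted classification, input-frequency band labels,
a normality ("Gaussian PDF") filter over per-trial MSF samples, van Rossum
spike-distance matrices, mapping of MSF values onto in-vitro developmental
reference windows, and balanced fixed-effects factorial ANOVA.

MSF convention: total spike count after the burn-in divided by
``N * (T - burn_in)`` — the network-mean per-neuron rate in Hz.  The values
this pipeline handles (units of 1-150 Hz) are per-neuron scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import SpikeRecord

__all__ = [
    "ModulationChange",
    "StageReference",
    "DEFAULT_STAGE_REFERENCES",
    "PdfFilterResult",
    "AnovaResult",
    "mean_spike_frequency",
    "percent_change",
    "classify_modulation",
    "band_label",
    "gaussian_pdf_filter",
    "spike_distance_matrix",
    "stage_map",
    "anova_factorial",
    "modulation_table",
]

STP_CLASSES = ("STD1", "STD2", "STF1", "STF2")

#: |percent change| below this is reported as direction "none".
DIRECTION_DEADBAND_PCT = 1.0


# --------------------------------------------------------------------------
# MSF and modulation arithmetic
# --------------------------------------------------------------------------

def mean_spike_frequency(rec: SpikeRecord, burn_in: float) -> float:
    """Network-mean per-neuron firing rate (Hz) over ``(burn_in, T]``."""
    if burn_in >= rec.duration:
        raise ValueError("burn_in must be smaller than the record duration")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    count = int(np.count_nonzero(rec.times > burn_in))
    return count / (rec.n_neurons * (rec.duration - burn_in))


@dataclass(frozen=True)
class ModulationChange:
    """Percent change of MSF between a control and an STP run.

    ``percent`` is signed (positive = reduction); ``magnitude`` is its
    absolute value, reported alongside ``direction`` the way the source
    tables phrase it ("x% reduction/increase")."""

    percent: float
    direction: str  # reduction | increase | none

    @property
    def magnitude(self) -> float:
        return abs(self.percent)

    def rounded(self, ndigits: int = 1) -> float:
        """Round-half-even magnitude, one decimal by default."""
        return round(self.magnitude, ndigits) if ndigits else float(
            round(self.magnitude)
        )


def percent_change(before: float, after: float) -> ModulationChange:
    """Signed percent change ``100*(before-after)/before`` with direction.

    Positive values are reductions.  Changes smaller than 1% in magnitude
    are labeled direction "none" to avoid unstable labels on noise.
    """
    if before <= 0:
        raise ValueError("baseline MSF must be positive")
    pct = 100.0 * (before - after) / before
    if abs(pct) < DIRECTION_DEADBAND_PCT:
        direction = "none"
    elif pct > 0:
        direction = "reduction"
    else:
        direction = "increase"
    return ModulationChange(percent=pct, direction=direction)


def classify_modulation(stp_class: str, direction: str) -> str:
    """Predicted/unpredicted label for an STP-induced rate change.

    Depressing variants are expected to reduce the rate, facilitating ones
    to increase it; the opposite direction is "unpredicted".  A "none"
    direction yields "none".  The control class has no label (error).
    """
    key = stp_class.upper()
    if key in ("CONTROL", "NONE"):
        raise ValueError("control runs carry no modulation label")
    if key not in STP_CLASSES:
        raise ValueError(f"unknown STP class {stp_class!r}")
    if direction == "none":
        return "none"
    if direction not in ("reduction", "increase"):
        raise ValueError(f"unknown direction {direction!r}")
    depressing = key.startswith("STD")
    if depressing:
        return "predicted" if direction == "reduction" else "unpredicted"
    return "predicted" if direction == "increase" else "unpredicted"


#: (name, lower, upper) with lower-exclusive / upper-inclusive convention,
#: chosen so the 5..100 Hz grid lands where the source tables place it
#: (30 Hz beta, 50 Hz low-gamma, 80 Hz high-gamma, 85 Hz epsilon).
_BANDS = (
    ("theta", 3.0, 7.0),
    ("alpha", 7.0, 12.0),
    ("beta", 12.0, 30.0),
    ("low-gamma", 30.0, 50.0),
    ("high-gamma", 50.0, 80.0),
    ("epsilon", 80.0, 250.0),
)


def band_label(IF: float) -> str:
    """Frequency-band name for an input frequency in (3, 250] Hz."""
    if not 0 < IF <= 250:
        raise ValueError("IF must lie in (0, 250] Hz")
    for name, lo, hi in _BANDS:
        if lo < IF <= hi:
            return name
    raise ValueError(f"IF = {IF} Hz is below the labeled bands (> 3 Hz required)")


# --------------------------------------------------------------------------
# Per-condition trial filtering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PdfFilterResult:
    keep: bool
    statistic: float
    pvalue: float
    reason: str


def gaussian_pdf_filter(trial_msfs, alpha: float = 0.05) -> PdfFilterResult:
    """Keep/exclude a condition by normality of its per-trial MSF sample.

    Fits a Gaussian to the trials and rejects the condition when a
    Shapiro-Wilk test rejects normality at ``alpha``.  Degenerate samples
    (zero variance) are excluded with a diagnostic.
    """
    y = np.asarray(trial_msfs, dtype=float)
    if y.size < 3:
        raise ValueError("at least 3 trials are required")
    if np.ptp(y) == 0:
        return PdfFilterResult(
            keep=False, statistic=math.nan, pvalue=math.nan,
            reason="degenerate fit: zero variance across trials",
        )
    stat, p = stats.shapiro(y)
    keep = p >= alpha
    reason = (
        f"Shapiro-Wilk W={stat:.4f}, p={p:.4g} "
        f"({'kept' if keep else 'excluded'} at alpha={alpha})"
    )
    return PdfFilterResult(keep=keep, statistic=float(stat), pvalue=float(p),
                           reason=reason)


# --------------------------------------------------------------------------
# Spike-train distance
# --------------------------------------------------------------------------

def _exp_prefix(train: np.ndarray, tau: float) -> np.ndarray:
    """E_k = sum_{i<=k} exp(-(t_k - t_i)/tau) for a sorted train (O(n))."""
    n = train.size
    E = np.empty(n)
    acc = 0.0
    prev = 0.0
    for k in range(n):
        if k:
            acc = (acc + 1.0) * math.exp(-(train[k] - prev) / tau)
        E[k] = acc  # excludes the self term exp(0)
        prev = train[k]
    return E


def _kernel_cross_sum(a: np.ndarray, b: np.ndarray, tau: float,
                      Ea: np.ndarray, Eb: np.ndarray) -> float:
    """sum_{i,j} exp(-|a_i - b_j|/tau) using per-train prefix sums."""
    total = 0.0
    for query, ref, Eref in ((b, a, Ea), (a, b, Eb)):
        if ref.size == 0:
            continue
        idx = np.searchsorted(ref, query, side="right")
        valid = idx > 0
        if not np.any(valid):
            continue
        last = ref[idx[valid] - 1]
        decay = np.exp(-(query[valid] - last) / tau)
        total += float(np.sum(decay * (Eref[idx[valid] - 1] + 1.0)))
    # spikes at exactly equal times are counted on both passes; subtract once
    common = np.intersect1d(a, b)
    if common.size:
        # each exact coincidence contributed exp(0)=1 twice
        counts_a = np.searchsorted(a, common, side="right") - np.searchsorted(a, common)
        counts_b = np.searchsorted(b, common, side="right") - np.searchsorted(b, common)
        total -= float(np.sum(counts_a * counts_b))
    return total


def _vr_self_sum(train: np.ndarray, tau: float, E: np.ndarray) -> float:
    return train.size + 2.0 * float(E.sum())


def van_rossum_distance(a, b, tau: float) -> float:
    """van Rossum distance with a causal exponential kernel (tau in the same
    unit as the spike times).  Identical trains give 0; two single-spike
    trains offset by ``d`` give ``sqrt(1 - exp(-d/tau))``."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    Ea = _exp_prefix(a, tau)
    Eb = _exp_prefix(b, tau)
    aa = _vr_self_sum(a, tau, Ea)
    bb = _vr_self_sum(b, tau, Eb)
    ab = _kernel_cross_sum(a, b, tau, Ea, Eb)
    d2 = 0.5 * (aa + bb - 2.0 * ab)
    return math.sqrt(max(d2, 0.0))


def spike_distance_matrix(
    rec: SpikeRecord,
    subsample: int = 100,
    kernel_tau: float = 20.0,
    burn_in: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise van Rossum distances between subsampled neurons.

    ``kernel_tau`` is in ms; spike times are seconds.  Returns the symmetric
    matrix (zero diagonal) and the subsampled neuron ids.
    """
    if rec.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    rng = np.random.default_rng(seed)
    k = min(subsample, rec.n_neurons)
    ids = np.sort(rng.choice(rec.n_neurons, size=k, replace=False))
    tau_s = kernel_tau / 1000.0
    trains = [rec.train(i) for i in ids]
    trains = [t[t > burn_in] for t in trains]
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = van_rossum_distance(trains[i], trains[j], tau_s)
    return mat, ids


# --------------------------------------------------------------------------
# Developmental stage mapping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageReference:
    """In-vitro MSF reference window: mean +/- sd in Hz."""

    label: str
    mean: float
    sd: float


DEFAULT_STAGE_REFERENCES = (
    StageReference("pre-shift 5-10 DIV", 7.86, 1.30),
    StageReference("shift 11-17 DIV", 54.27, 7.22),
)


def stage_map(msf: float, refs=DEFAULT_STAGE_REFERENCES, k: float = 2.0) -> str:
    """Label of the reference window whose mean +/- k*sd contains ``msf``;
    nearer mean wins ties; "outside" when no window matches."""
    if msf < 0:
        raise ValueError("MSF must be non-negative")
    hits = [r for r in refs if r.mean - k * r.sd <= msf <= r.mean + k * r.sd]
    if not hits:
        return "outside"
    return min(hits, key=lambda r: abs(msf - r.mean)).label


# --------------------------------------------------------------------------
# Factorial ANOVA (balanced fixed-effects)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """Per-term decomposition; ``table`` rows are main effects, interactions
    (colon-joined names) and "Residual"."""

    table: pd.DataFrame
    n_obs: int

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnovaResult(n={self.n_obs})\n{self.table}"


def anova_factorial(
    table: pd.DataFrame, factors: list[str], response: str = "msf_hz"
) -> AnovaResult:
    """Fixed-effects factorial ANOVA with all interactions.

    Requires a balanced complete design (equal cell counts), which the sweep
    produces; on balanced data sequential/marginal sums of squares coincide.
    Sums of squares use the standard marginal-means inclusion-exclusion.
    Handles 1, 2 or 3 factors (one factor reduces to one-way ANOVA).
    """
    if not factors:
        raise ValueError("at least one factor is required")
    df = table.dropna(subset=[response])
    y = df[response].to_numpy(float)
    n = y.size
    levels = {f: np.unique(df[f].to_numpy()) for f in factors}
    for f, lv in levels.items():
        if lv.size < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    n_cells = int(np.prod([lv.size for lv in levels.values()]))
    cell_counts = df.groupby(factors, observed=True)[response].count()
    if cell_counts.size != n_cells or cell_counts.nunique() != 1:
        raise ValueError("design must be balanced and complete")

    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    # effect estimates per factor subset via inclusion-exclusion
    effects: dict[tuple[str, ...], pd.Series] = {}
    rows = []
    ss_model = 0.0
    for size in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, size):
            marg = df.groupby(list(subset), observed=True)[response].mean()
            eff = marg - grand
            for smaller_size in range(1, size):
                for smaller in itertools.combinations(subset, smaller_size):
                    sub_eff = effects[smaller]
                    # broadcast the lower-order effect over the finer margin
                    idx = marg.index.to_frame(index=False)
                    key = (
                        idx[list(smaller)].iloc[:, 0]
                        if len(smaller) == 1
                        else pd.MultiIndex.from_frame(idx[list(smaller)])
                    )
                    eff = eff - sub_eff.loc[key].to_numpy()
            effects[subset] = eff
            reps = n / eff.size
            ss = float(reps * np.sum(eff.to_numpy() ** 2))
            dfree = int(np.prod([levels[f].size - 1 for f in subset]))
            ss_model += ss
            rows.append({"term": ":".join(subset), "sum_sq": ss, "df": dfree})

    ss_res = ss_total - ss_model
    df_res = n - n_cells
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (need replicates)")
    ms_res = ss_res / df_res
    for row in rows:
        ms = row["sum_sq"] / row["df"]
        row["F"] = ms / ms_res
        row["PR(>F)"] = float(stats.f.sf(row["F"], row["df"], df_res))
    rows.append(
        {"term": "Residual", "sum_sq": ss_res, "df": df_res,
         "F": np.nan, "PR(>F)": np.nan}
    )
    out = pd.DataFrame(rows).set_index("term")
    return AnovaResult(table=out, n_obs=n)


# --------------------------------------------------------------------------
# Condition-level modulation summary
# --------------------------------------------------------------------------

def modulation_table(msf_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Collapse a tidy MSF table into per-condition modulation records.

    For every (scenario, maturation, stp_class != control, IF) cell with a
    matching control cell: average the trial MSFs (after the Gaussian-PDF
    trial filter), compute the percent change against control, and attach
    the predicted/unpredicted label.  Cells failing the filter are kept with
    ``included = False``.
    """
    keys = ["scenario", "maturation", "IF_hz"]
    recs = []
    for key_vals, group in msf_table.groupby(keys, observed=True):
        ctrl = group[group["stp_class"] == "control"]["msf_hz"].dropna()
        if ctrl.empty:
            continue
        ctrl_filter = (
            gaussian_pdf_filter(ctrl, alpha)
            if ctrl.size >= 3
            else PdfFilterResult(True, math.nan, math.nan, "too few trials to test")
        )
        before = float(ctrl.mean())
        for stp_class in STP_CLASSES:
            cell = group[group["stp_class"] == stp_class]["msf_hz"].dropna()
            if cell.empty:
                continue
            cell_filter = (
                gaussian_pdf_filter(cell, alpha)
                if cell.size >= 3
                else PdfFilterResult(True, math.nan, math.nan, "too few trials to test")
            )
            after = float(cell.mean())
            change = percent_change(before, after)
            recs.append(
                dict(
                    zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,))
                )
                | {
                    "stp_class": stp_class,
                    "band": band_label(float(group["IF_hz"].iloc[0])),
                    "msf_before": before,
                    "msf_after": after,
                    "percent_change": change.rounded(1),
                    "direction": change.direction,
                    "label": classify_modulation(stp_class, change.direction),
                    "included": bool(ctrl_filter.keep and cell_filter.keep),
                    "filter_note": cell_filter.reason,
                }
            )
    return pd.DataFrame(recs)
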
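"""Within-person time-series characteristics of normalized EMA items.

All operations take a single person x item series laid out on the fixed
beep grid: a float array of length 84 with NaN in unobserved slots.
Lagged statistics (RMSSD, lag-1 autocorrelation) use only *valid pairs* —
consecutive beeps that are both observed — because a missing beep can
neither predict nor be predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FIRST_DAY_BEEPS, N_BEEPS, StudyDataset

logger = logging.getLogger("emascale")


def _observed(series) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    return arr[np.isfinite(arr)]


def wp_moments(series) -> dict:
    """Mean, sample SD (n-1 divisor) and g1 skewness of the observed values.

    Skewness uses the moment estimator g1 = m3 / m2^(3/2) with n-divisor
    central moments; it is undefined (NaN) for constant series, as is the
    SD for n < 2.
    """
    vals = _observed(series)
    n = len(vals)
    if n == 0:
        return {"mean": np.nan, "sd": np.nan, "skew": np.nan, "n": 0}
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n >= 2 else np.nan
    m2 = float(np.mean((vals - mean) ** 2))
    if m2 > 0:
        skew = float(np.mean((vals - mean) ** 3) / m2**1.5)
    else:
        skew = np.nan
    return {"mean": mean, "sd": sd, "skew": skew, "n": n}


def _valid_pairs(series, exclude_overnight: bool = False) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(series, dtype=float)
    a, b = arr[:-1], arr[1:]
    ok = np.isfinite(a) & np.isfinite(b)
    if exclude_overnight:
        # pairs crossing a day boundary: beep 6 -> 7, 12 -> 13, ...
        t = np.arange(len(arr) - 1)
        ok &= (t + 1) % FIRST_DAY_BEEPS != 0
    return a[ok], b[ok]


def wp_rmssd(series, exclude_overnight: bool = False) -> dict:
    """Root mean squared successive difference over valid beep pairs."""
    a, b = _valid_pairs(series, exclude_overnight)
    n_pairs = len(a)
    if n_pairs == 0:
        return {"rmssd": np.nan, "n_pairs": 0}
    return {"rmssd": float(np.sqrt(np.mean((b - a) ** 2))), "n_pairs": n_pairs}


def wp_ar1(series, exclude_overnight: bool = False) -> dict:
    """Lag-1 autocorrelation: Pearson r over the valid-pair set."""
    a, b = _valid_pairs(series, exclude_overnight)
    n_pairs = len(a)
    if n_pairs < 2 or np.std(a) == 0 or np.std(b) == 0:
        return {"ar1": np.nan, "n_pairs": n_pairs}
    r = float(np.corrcoef(a, b)[0, 1])
    return {"ar1": r, "n_pairs": n_pairs}


def count_modes(
    series,
    jitter_sd: float = 0.02,
    bandwidth_rule: str = "silverman",
    grid_size: int = 512,
    replicates: int = 10,
    rng_seed: int = 0,
    min_rel_height: float = 0.05,
    spacing: float = 0.0,
) -> int:
    """Density-estimation mode count of an item's response distribution.

    Responses are discrete, so before density estimation each value is
    dequantized with uniform noise over its rounding interval (``spacing``
    is the response resolution: 1/6 for the normalized 7-point scale,
    1/100 for the VAS) plus a small Gaussian jitter; without the
    dequantization the detector would count the category grid itself as
    modes.  A Gaussian KDE is then fit on an even unit-interval grid and
    strict local maxima are counted (grid endpoints included).  Maxima
    below ``min_rel_height`` of the density peak are ignored — isolated
    tail observations otherwise register as spurious modes.  The count is
    the majority vote over jitter replicates; ties break toward the
    smaller count.  Deterministic given ``rng_seed``.
    """
    vals = _observed(series)
    if len(vals) == 0:
        raise ValueError("count_modes requires at least one observed value")
    rng = np.random.default_rng(rng_seed)
    grid = np.linspace(0.0, 1.0, grid_size)
    counts = []
    for _ in range(replicates):
        jittered = vals + rng.normal(0.0, jitter_sd, size=len(vals))
        if spacing > 0:
            jittered = jittered + rng.uniform(-spacing / 2, spacing / 2, size=len(vals))
        if np.std(jittered) == 0:
            counts.append(1)
            continue
        kde = sps.gaussian_kde(jittered, bw_method=bandwidth_rule)
        dens = kde(grid)
        is_max = np.zeros(grid_size, dtype=bool)
        is_max[1:-1] = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        is_max[0] = dens[0] > dens[1]
        is_max[-1] = dens[-1] > dens[-2]
        is_max &= dens >= min_rel_height * dens.max()
        counts.append(max(int(is_max.sum()), 1))
    votes = np.bincount(counts)
    return int(np.argmax(votes))


@dataclass
class CorrMatrix:
    """Within-person item correlation matrix with per-cell pair counts."""

    values: np.ndarray  # (k, k), NaN where undefined
    pair_counts: np.ndarray  # (k, k) ints
    items: list


def wp_corr_matrix(mat: np.ndarray, items: list | None = None, min_pairs: int = 3) -> CorrMatrix:
    """Pairwise-complete Pearson correlations across one person's items.

    ``mat`` is (n_items, 84).  A cell is undefined (NaN) when fewer than
    ``min_pairs`` overlapping beeps exist or either item lacks variation on
    the overlap; zero-variance items yield an undefined row/column.
    """
    mat = np.asarray(mat, dtype=float)
    k = mat.shape[0]
    items = items if items is not None else list(range(k))
    finite = np.isfinite(mat)
    R = np.full((k, k), np.nan)
    counts = np.zeros((k, k), dtype=int)
    np.fill_diagonal(R, 1.0)
    if not finite.any():
        return CorrMatrix(R, counts, items)
    if finite.all():
        with np.errstate(invalid="ignore"):
            sd = mat.std(axis=1)
            full = np.corrcoef(mat)
        full[sd == 0, :] = np.nan
        full[:, sd == 0] = np.nan
        np.fill_diagonal(full, np.where(sd == 0, np.nan, 1.0))
        counts[:] = mat.shape[1]
        return CorrMatrix(full, counts, items)
    for i in range(k):
        for j in range(i + 1, k):
            ok = finite[i] & finite[j]
            counts[i, j] = counts[j, i] = int(ok.sum())
            if counts[i, j] < min_pairs:
                continue
            x, y = mat[i, ok], mat[j, ok]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            R[i, j] = R[j, i] = float(np.corrcoef(x, y)[0, 1])
    return CorrMatrix(R, counts, items)


def mean_abs_corr(cm: CorrMatrix, item_index: int) -> float:
    """Mean |r| of one item with all other items (defined cells only)."""
    row = np.delete(cm.values[item_index], item_index)
    ok = np.isfinite(row)
    if not ok.any():
        return np.nan
    return float(np.mean(np.abs(row[ok])))


def group_corr_summary(matrices: list[CorrMatrix]) -> dict:
    """Unweighted per-cell mean over participants, plus eigenvalues.

    Eigen-decomposition is skipped (with a warning) when any cell is
    undefined for every participant.
    """
    if not matrices:
        raise ValueError("need at least one correlation matrix")
    stack = np.stack([m.values for m in matrices])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    out = {"mean_matrix": mean, "eigenvalues": None}
    if np.isfinite(mean).all():
        out["eigenvalues"] = np.sort(np.linalg.eigvalsh(mean))[::-1]
    else:
        logger.warning("group_corr_summary: undefined cells; skipping eigen-decomposition")
    return out


def corr_structure_similarity(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    """Pearson correlation of the 91 off-diagonal cells across two groups."""
    iu = np.triu_indices_from(mean_a, k=1)
    a, b = mean_a[iu], mean_b[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def initial_elevation(series) -> float:
    """Mean of day-1 beeps (1-6) minus the mean of the remaining beeps."""
    arr = np.asarray(series, dtype=float)
    first = arr[:FIRST_DAY_BEEPS]
    rest = arr[FIRST_DAY_BEEPS:]
    if not (np.isfinite(first).any() and np.isfinite(rest).any()):
        return np.nan
    return float(np.nanmean(first) - np.nanmean(rest))


def missing_proportion(n_completed_beeps: int, t_max: int = N_BEEPS) -> float:
    """1 - completed/possible beeps."""
    return 1.0 - n_completed_beeps / t_max


# ---------------------------------------------------------------------------
# study-level assembly


def participant_corr_matrices(dataset: StudyDataset) -> dict:
    """participant_id -> CorrMatrix over the 14 items."""
    pids, arr, _ = dataset.stacked_arrays()
    return {pid: wp_corr_matrix(arr[i], dataset.item_names) for i, pid in enumerate(pids)}


def compute_stat_table(
    dataset: StudyDataset,
    include_modes: bool = False,
    mode_seed: int = 0,
    exclude_overnight: bool = False,
) -> pd.DataFrame:
    """The per-(participant, item) statistic battery as one long table.

    Columns: wp_mean, wp_sd, wp_skew, n_obs, rmssd, ar1, n_pairs,
    mean_abs_corr, init_elev, optional n_modes, plus the per-participant
    missing_prop, mean duration and lag-eligibility flag repeated on each
    row.  Mode counting is optional because it is by far the slowest
    statistic.
    """
    pids, arr, groups = dataset.stacked_arrays()
    valence = {it.name: it.valence for it in dataset.items}
    dur = dataset.records.groupby("participant_id")["duration_s"].mean()
    rows = []
    for i, pid in enumerate(pids):
        cm = wp_corr_matrix(arr[i], dataset.item_names)
        n_completed = int(np.isfinite(arr[i]).any(axis=0).sum())
        miss = missing_proportion(n_completed)
        for j, item in enumerate(dataset.item_names):
            series = arr[i, j]
            mom = wp_moments(series)
            rms = wp_rmssd(series, exclude_overnight)
            ac = wp_ar1(series, exclude_overnight)
            row = {
                "participant_id": pid,
                "group": groups[i],
                "item": item,
                "valence": valence[item],
                "n_obs": mom["n"],
                "wp_mean": mom["mean"],
                "wp_sd": mom["sd"],
                "wp_skew": mom["skew"],
                "n_pairs": rms["n_pairs"],
                "rmssd": rms["rmssd"],
                "ar1": ac["ar1"],
                "mean_abs_corr": mean_abs_corr(cm, j),
                "init_elev": initial_elevation(series),
                "missing_prop": miss,
                "mean_duration": float(dur.get(pid, np.nan)),
                "lag_eligible": dataset.lag_eligible.get(pid, True),
            }
            if include_modes:
                spacing = 1.0 / 6.0 if groups[i] == "likert" else 1.0 / 100.0
                row["n_modes"] = (
                    count_modes(series, rng_seed=mode_seed + 1000 * i + j, spacing=spacing)
                    if mom["n"] >= 20
                    else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
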
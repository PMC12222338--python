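"""Data model and I/O for two-arm EMA response-scale studies.

A study compares two groups of participants answering the same 14 momentary
affect items (5 positive, 9 negative valence) up to 84 times (6 beeps/day
over 14 days), one group on a 7-point Likert scale, the other on a 0-100
visual-analogue scale (VAS).  Both scales are normalized to the unit
interval before any statistic is computed, so every downstream module works
on [0, 1] series with explicit missing slots.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("emascale")

#: number of scheduled beeps per participant (6 per day x 14 days)
N_BEEPS = 84

#: first-day beeps used for the initial-elevation window
FIRST_DAY_BEEPS = 6


class ResponseScale(enum.Enum):
    """Response format of a study arm."""

    LIKERT7 = "likert"
    VAS101 = "vas"

    @classmethod
    def from_label(cls, label: str) -> "ResponseScale":
        label = str(label).strip().lower()
        for scale in cls:
            if label == scale.value or label == scale.name.lower():
                return scale
        raise ValueError(f"unknown group label {label!r}; expected 'likert' or 'vas'")


@dataclass(frozen=True)
class ItemSpec:
    """One momentary affect item with its valence."""

    name: str
    valence: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.valence not in ("positive", "negative"):
            raise ValueError(f"valence must be positive/negative, got {self.valence!r}")


#: the default item catalogue: 5 positive and 9 negative affect items
DEFAULT_ITEMS: tuple[ItemSpec, ...] = (
    ItemSpec("Happy", "positive"),
    ItemSpec("Energetic", "positive"),
    ItemSpec("Looking forward", "positive"),
    ItemSpec("Satisfied self", "positive"),
    ItemSpec("Satisfied body", "positive"),
    ItemSpec("Sad", "negative"),
    ItemSpec("Guilty", "negative"),
    ItemSpec("Ashamed", "negative"),
    ItemSpec("Disgusted", "negative"),
    ItemSpec("Anxious", "negative"),
    ItemSpec("Irritated", "negative"),
    ItemSpec("Physical discomfort", "negative"),
    ItemSpec("Lonely", "negative"),
    ItemSpec("Stressed", "negative"),
)

CRITERION_COLUMNS = ("bsi", "dass_dep", "dass_anx", "dass_stress")

_RECORD_COLUMNS = ["participant_id", "group", "item", "beep", "value", "value_norm", "duration_s"]


def normalize_response(raw, scale: ResponseScale):
    """Map a raw response to the unit interval.

    Likert 1..7 -> (raw - 1)/6; VAS 0..100 -> raw/100.  Accepts scalars or
    arrays; raises on out-of-range values.
    """
    arr = np.asarray(raw, dtype=float)
    if scale is ResponseScale.LIKERT7:
        if np.any((arr < 1) | (arr > 7)):
            raise ValueError(f"Likert responses must lie in 1..7, got {raw!r}")
        out = (arr - 1.0) / 6.0
    elif scale is ResponseScale.VAS101:
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError(f"VAS responses must lie in 0..100, got {raw!r}")
        out = arr / 100.0
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown scale {scale!r}")
    return float(out) if np.isscalar(raw) else out


@dataclass
class InclusionConfig:
    """Participant inclusion thresholds.

    ``min_obs``: minimum completed beeps to enter the analysis at all.
    ``min_pairs``: minimum valid consecutive beep pairs for eligibility of
    the lagged statistics (RMSSD, lag-1 autocorrelation).
    """

    min_obs: int = 20
    min_pairs: int = 20

    def __post_init__(self) -> None:
        if self.min_obs < 1 or self.min_pairs < 1:
            raise ValueError("inclusion thresholds must be >= 1")


@dataclass
class StudyDataset:
    """Long-format records plus item metadata and baseline criterion scores.

    ``records`` has one row per observed participant x beep x item with the
    raw and the normalized response.  Missing beeps are simply absent rows.
    ``criteria`` is indexed by participant_id with columns
    bsi, dass_dep, dass_anx, dass_stress (may be empty).
    """

    records: pd.DataFrame
    items: tuple[ItemSpec, ...] = DEFAULT_ITEMS
    criteria: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(CRITERION_COLUMNS)))
    lag_eligible: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        groups = self.records.groupby("participant_id")["group"].nunique()
        if (groups > 1).any():
            bad = groups[groups > 1].index.tolist()
            raise ValueError(f"participants assigned to more than one group: {bad}")

    # -- convenience accessors -------------------------------------------------

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def valences(self) -> np.ndarray:
        return np.array([it.valence for it in self.items])

    def participants(self) -> list:
        return sorted(self.records["participant_id"].unique().tolist())

    def group_of(self) -> pd.Series:
        """participant_id -> group label ('likert'/'vas')."""
        return self.records.groupby("participant_id")["group"].first()

    def n_obs_beeps(self) -> pd.Series:
        """participant_id -> number of beeps with at least one recorded item."""
        return self.records.groupby("participant_id")["beep"].nunique()

    def participant_matrix(self, pid) -> np.ndarray:
        """(n_items, 84) normalized values with NaN in missing slots."""
        sub = self.records[self.records["participant_id"] == pid]
        mat = np.full((len(self.items), N_BEEPS), np.nan)
        idx = {name: i for i, name in enumerate(self.item_names)}
        rows = sub["item"].map(idx).to_numpy()
        cols = sub["beep"].to_numpy(dtype=int) - 1
        mat[rows, cols] = sub["value_norm"].to_numpy(dtype=float)
        return mat

    def stacked_arrays(self) -> tuple[list, np.ndarray, np.ndarray]:
        """All participants at once: (pids, values (n, items, 84), group labels)."""
        pids = self.participants()
        idx = {name: i for i, name in enumerate(self.item_names)}
        pidx = {p: i for i, p in enumerate(pids)}
        arr = np.full((len(pids), len(self.items), N_BEEPS), np.nan)
        r = self.records
        arr[
            r["participant_id"].map(pidx).to_numpy(),
            r["item"].map(idx).to_numpy(),
            r["beep"].to_numpy(dtype=int) - 1,
        ] = r["value_norm"].to_numpy(dtype=float)
        groups = self.group_of().reindex(pids).to_numpy()
        return pids, arr, groups

    def subset(self, pids) -> "StudyDataset":
        keep = set(pids)
        rec = self.records[self.records["participant_id"].isin(keep)].reset_index(drop=True)
        crit = self.criteria[self.criteria.index.isin(keep)]
        elig = {p: v for p, v in self.lag_eligible.items() if p in keep}
        return StudyDataset(rec, self.items, crit, elig)


def _valid_pair_count(beeps: np.ndarray) -> int:
    """Number of consecutive beep pairs (t, t+1) that are both observed."""
    present = np.zeros(N_BEEPS, dtype=bool)
    present[np.asarray(beeps, dtype=int) - 1] = True
    return int(np.sum(present[:-1] & present[1:]))


def apply_inclusion(dataset: StudyDataset, cfg: InclusionConfig | None = None) -> StudyDataset:
    """Drop participants with fewer than ``min_obs`` completed beeps.

    Also annotates each retained participant with a lag-eligibility flag:
    lagged statistics (RMSSD, AR(1)) require at least ``min_pairs`` valid
    consecutive beep pairs, so their effective sample is smaller.
    Idempotent; exclusion counts are logged.
    """
    cfg = cfg or InclusionConfig()
    if dataset.records.empty:
        logger.warning("apply_inclusion: empty dataset")
        return dataset
    n_obs = dataset.n_obs_beeps()
    keep = n_obs[n_obs >= cfg.min_obs].index
    n_excluded = int(len(n_obs) - len(keep))
    if n_excluded:
        logger.info("inclusion filter: excluded %d participants with < %d observed beeps", n_excluded, cfg.min_obs)
    out = dataset.subset(keep)
    pair_counts = out.records.groupby("participant_id")["beep"].agg(
        lambda b: _valid_pair_count(b.unique())
    )
    out.lag_eligible = {p: bool(c >= cfg.min_pairs) for p, c in pair_counts.items()}
    return out


def detect_careless(dataset: StudyDataset, frac_threshold: float = 1.0) -> pd.Series:
    """Flag participants whose completed beeps are (almost) all constant rows.

    A completed beep is one with every item recorded; it counts as constant
    when all item responses at that beep are identical.  A participant is
    flagged when the fraction of constant completed beeps is >= the
    threshold (default 1.0: every single completed beep constant).  Flagged
    participants are reported, never removed automatically.
    """
    flags = {}
    n_items = len(dataset.items)
    for pid, sub in dataset.records.groupby("participant_id"):
        counts = sub.groupby("beep")["value_norm"].agg(["count", "nunique"])
        completed = counts[counts["count"] == n_items]
        if len(completed) == 0:
            logger.warning("detect_careless: participant %s has no completed beeps", pid)
            flags[pid] = False
            continue
        frac_constant = float((completed["nunique"] == 1).mean())
        flags[pid] = frac_constant >= frac_threshold
    return pd.Series(flags, name="careless").sort_index()


# -- I/O ------------------------------------------------------------------------


def read_study(
    path,
    criteria_path=None,
    items: tuple[ItemSpec, ...] = DEFAULT_ITEMS,
    schema: dict | None = None,
) -> tuple[StudyDataset, pd.DataFrame]:
    """Read a long-format study CSV, normalizing raw values on load.

    Expected columns (renameable through ``schema``): participant_id,
    group in {likert, vas}, item, beep in 1..84, value (raw integer),
    duration_s (optional).  Malformed rows are collected into an error
    report (second return value) rather than aborting the load.
    """
    raw = pd.read_csv(path)
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    needed = ["participant_id", "group", "item", "beep", "value"]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValueError(f"study file missing columns {missing}")
    if "duration_s" not in raw.columns:
        raw["duration_s"] = np.nan

    item_names = {it.name for it in items}
    errors = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False)):
        try:
            scale = ResponseScale.from_label(row.group)
            beep = int(row.beep)
            if not 1 <= beep <= N_BEEPS:
                raise ValueError(f"beep {beep} outside 1..{N_BEEPS}")
            if row.item not in item_names:
                raise ValueError(f"unknown item {row.item!r}")
            value = float(row.value)
            if value != int(value):
                raise ValueError(f"non-integer raw value {row.value!r}")
            vnorm = normalize_response(int(value), scale)
        except (ValueError, TypeError) as exc:
            errors.append({"row": i, "reason": str(exc)})
            continue
        rows.append(
            (row.participant_id, scale.value, row.item, beep, int(value), vnorm,
             float(row.duration_s) if pd.notna(row.duration_s) else np.nan)
        )
    records = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    error_report = pd.DataFrame(errors, columns=["row", "reason"])
    if len(error_report):
        logger.warning("read_study: rejected %d malformed rows", len(error_report))

    if criteria_path is not None:
        crit = pd.read_csv(criteria_path).set_index("participant_id")
        crit = crit[[c for c in CRITERION_COLUMNS if c in crit.columns]]
    else:
        crit = pd.DataFrame(columns=list(CRITERION_COLUMNS))
    return StudyDataset(records, items, crit), error_report


def write_study(dataset: StudyDataset, path, criteria_path=None) -> None:
    """Write the long-format records (and optionally criteria) as CSV."""
    dataset.records.to_csv(path, index=False)
    if criteria_path is not None and len(dataset.criteria):
        dataset.criteria.rename_axis("participant_id").to_csv(criteria_path)
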
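"""Permutation inference on within-person correlation matrices, and the
participant-level (cluster) bootstrap.

The permutation test asks, for each of the 91 item pairs, whether the mean
within-person correlation differs between the Likert and VAS arms.  Whole
participants move between groups when labels are shuffled, preserving the
within-person dependence structure that makes an SEM-style equality test
inapplicable here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StudyDataset

logger = logging.getLogger("emascale")


@dataclass
class PermutationResult:
    """Per-pair observed VAS-Likert mean-correlation differences and p values."""

    table: pd.DataFrame  # item_a, item_b, obs_diff, p_value, significant
    n_permutations: int
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def corr_vectors(matrices: dict, item_names: list[str]) -> tuple[np.ndarray, list, list[tuple]]:
    """Stack each participant's upper-triangle correlations into (n, 91)."""
    k = len(item_names)
    iu = np.triu_indices(k, k=1)
    pids = sorted(matrices)
    vecs = np.stack([matrices[p].values[iu] for p in pids])
    pairs = [(item_names[i], item_names[j]) for i, j in zip(*iu)]
    return vecs, pids, pairs


def permutation_corr_test(
    matrices: dict,
    groups: pd.Series,
    item_names: list[str],
    n_perm: int = 500,
    alpha: float = 0.10,
    seed: int = 0,
) -> PermutationResult:
    """Label-shuffling test of equal mean within-person correlations.

    Statistic per pair: mean r over VAS participants minus mean r over
    Likert participants (pairwise participant deletion for undefined
    cells).  Two-sided empirical p with the add-one correction
    p = (1 + #{|perm| >= |obs|}) / (n_perm + 1), so p is never 0.
    """
    vecs, pids, pairs = corr_vectors(matrices, item_names)
    labels = groups.reindex(pids).to_numpy()
    is_vas = labels == "vas"
    n_vas, n_lik = int(is_vas.sum()), int((~is_vas).sum())
    if min(n_vas, n_lik) < 2:
        raise ValueError("need >= 2 participants per group")

    finite = np.isfinite(vecs)
    defined_vas = finite[is_vas].sum(axis=0)
    defined_lik = finite[~is_vas].sum(axis=0)
    usable = (defined_vas > 0) & (defined_lik > 0)
    if not usable.all():
        logger.warning("permutation test: %d pairs undefined in one group, skipped", int((~usable).sum()))

    filled = np.where(finite, vecs, 0.0)

    def group_mean_diff(vas_mask: np.ndarray) -> np.ndarray:
        nv = finite[vas_mask].sum(axis=0).astype(float)
        nl = finite[~vas_mask].sum(axis=0).astype(float)
        sv = filled[vas_mask].sum(axis=0)
        sl = filled[~vas_mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return sv / nv - sl / nl

    obs = group_mean_diff(is_vas)
    rng = np.random.default_rng(seed)
    count_ge = np.zeros(vecs.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(len(pids))
        perm_mask = np.zeros(len(pids), dtype=bool)
        perm_mask[perm[:n_vas]] = True
        d = group_mean_diff(perm_mask)
        count_ge += np.abs(d) >= np.abs(obs)
    p = (1.0 + count_ge) / (n_perm + 1.0)
    p = np.where(usable, p, np.nan)

    table = pd.DataFrame(
        {
            "item_a": [a for a, _ in pairs],
            "item_b": [b for _, b in pairs],
            "obs_diff": np.where(usable, obs, np.nan),
            "p_value": p,
            "significant": (p <= alpha) & usable,
        }
    )
    return PermutationResult(table, n_perm, alpha)


def permutation_test_from_dataset(dataset: StudyDataset, n_perm: int = 500, alpha: float = 0.10, seed: int = 0) -> PermutationResult:
    from .descriptives import participant_corr_matrices

    matrices = participant_corr_matrices(dataset)
    return permutation_corr_test(matrices, dataset.group_of(), dataset.item_names, n_perm, alpha, seed)


def cluster_bootstrap(statistic, dataset: StudyDataset, B: int = 2000, seed: int = 0) -> list:
    """B replicates of ``statistic`` under participant resampling.

    Participants are drawn with replacement within their group; each keeps
    their full time series (resampled copies get suffixed ids so the
    replicate dataset still has one group per participant).  Replicates on
    which the statistic is undefined are recorded as None.
    """
    groups = dataset.group_of()
    pids_by_group = {g: np.array(sorted(groups[groups == g].index)) for g in groups.unique()}
    if sum(len(v) for v in pids_by_group.values()) < 2:
        raise ValueError("need >= 2 participants")
    rng = np.random.default_rng(seed)
    rec_by_pid = dict(tuple(dataset.records.groupby("participant_id")))

    out = []
    n_undefined = 0
    for _ in range(B):
        parts = []
        crit_rows = []
        for g, pids in pids_by_group.items():
            draw = pids[rng.integers(0, len(pids), size=len(pids))]
            for rep_i, p in enumerate(draw):
                sub = rec_by_pid[p].copy()
                new_id = f"{p}#{rep_i}"
                sub["participant_id"] = new_id
                parts.append(sub)
                if p in dataset.criteria.index:
                    row = dataset.criteria.loc[p].copy()
                    row.name = new_id
                    crit_rows.append(row)
        rec = pd.concat(parts, ignore_index=True)
        crit = pd.DataFrame(crit_rows) if crit_rows else dataset.criteria.iloc[0:0]
        rep = StudyDataset(rec, dataset.items, crit)
        try:
            val = statistic(rep)
            if val is None or (np.isscalar(val) and not np.isfinite(val)):
                raise ValueError("undefined statistic")
            out.append(val)
        except (ValueError, ZeroDivisionError):
            n_undefined += 1
            out.append(None)
    if n_undefined:
        logger.warning("cluster_bootstrap: %d/%d replicates undefined", n_undefined, B)
    return out
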
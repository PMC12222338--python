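"""Synthetic two-arm EMA study generator.

The generator emulates the data-generating structure the analysis assumes:
each person carries a latent affect level per item (item trait mean plus a
person factor shared within a valence block), beep-to-beep fluctuation is a
cross-sectionally correlated AR(1), the latent state is censored to [0, 1]
(producing exact-zero point masses for low-mean negative items), the VAS
arm reads the state at 0..100 granularity, and the Likert arm reads the
same kind of state through a 7-category threshold process.  Missingness is
MCAR at the beep level with person-specific rates; survey durations are
lognormal; baseline criterion scores load on the difference of the
negative- and positive-valence person factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import DEFAULT_ITEMS, N_BEEPS, CRITERION_COLUMNS, ItemSpec, StudyDataset
from .thresholding import ThresholdMap, vas_to_likert


@dataclass
class SyntheticConfig:
    """Generating parameters for one synthetic study.

    Group sizes, the beep grid, the item count/valence split, and the VAS
    missingness level are those of a two-week, six-beeps-per-day affect
    EMA design with two arms; dispersion and correlation defaults are
    chosen to land the within-person summary statistics in realistic
    ranges (within-person SDs around 0.13-0.15, clear valence block
    structure in the correlation matrices).
    """

    n_likert: int = 63
    n_vas: int = 56
    items: tuple[ItemSpec, ...] = DEFAULT_ITEMS
    t_max: int = N_BEEPS
    item_trait_means: tuple[float, ...] | None = None  # default 0.55 pos / 0.15 neg
    person_trait_sd: float = 0.12
    innovation_sd: float = 0.12
    ar_coef: float = 0.3
    within_valence_corr: float = 0.3
    between_valence_corr: float = -0.2
    missing_rate_mean: float = 0.33
    missing_rate_concentration: float = 10.0
    criterion_loading: float = 0.5
    duration_log_mean: float = math.log(135.0)
    duration_log_sd: float = 0.3
    likert_mechanism: str = "threshold_only"  # or "threshold_plus_zero_attraction"
    zero_attraction_cut: float = 0.10
    threshold_map: ThresholdMap = field(default_factory=ThresholdMap)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_likert < 1 or self.n_vas < 1:
            raise ValueError("group sizes must be >= 1")
        if not -1 < self.ar_coef < 1:
            raise ValueError("ar_coef must lie in (-1, 1)")
        if self.likert_mechanism not in ("threshold_only", "threshold_plus_zero_attraction"):
            raise ValueError(f"unknown likert_mechanism {self.likert_mechanism!r}")
        if self.item_trait_means is None:
            self.item_trait_means = tuple(
                0.55 if it.valence == "positive" else 0.15 for it in self.items
            )
        if len(self.item_trait_means) != len(self.items):
            raise ValueError("item_trait_means must match the item catalogue")
        if not all(0 < m < 1 for m in self.item_trait_means):
            raise ValueError("trait means must lie in (0, 1)")
        # fail early if the implied innovation correlation is not a correlation matrix
        innovation_correlation(self)

    def valence_codes(self) -> np.ndarray:
        return np.array([1.0 if it.valence == "negative" else 0.0 for it in self.items])


def default_config(**overrides) -> SyntheticConfig:
    """The default study conditions (two arms, 14 items, 84 beeps)."""
    return SyntheticConfig(**overrides)


def innovation_correlation(cfg: SyntheticConfig) -> np.ndarray:
    """Blocked innovation correlation: within-valence +, between-valence -.

    Raises when the implied matrix is not positive definite, naming the
    offending parameters.
    """
    neg = cfg.valence_codes()
    same = (neg[:, None] == neg[None, :])
    R = np.where(same, cfg.within_valence_corr, cfg.between_valence_corr)
    np.fill_diagonal(R, 1.0)
    evals = np.linalg.eigvalsh(R)
    if evals.min() <= 1e-10:
        raise ValueError(
            "implied innovation correlation is not positive definite "
            f"(within_valence_corr={cfg.within_valence_corr}, "
            f"between_valence_corr={cfg.between_valence_corr}, "
            f"min eigenvalue {evals.min():.3g})"
        )
    return R


def simulate_latent(
    cfg: SyntheticConfig,
    n_persons: int,
    rng: np.random.Generator,
    t_max: int | None = None,
    censor: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent (or censored) affect states for one arm.

    Returns (u, p_pos, p_neg): u has shape (n_persons, n_items, T) and is
    clamp(x, 0, 1) when ``censor`` else the raw latent x; p_pos/p_neg are
    the per-person valence-block factors.  The AR(1) is initialized from
    its stationary distribution, so the series have no transient.
    """
    T = t_max or cfg.t_max
    items = cfg.items
    k = len(items)
    R = innovation_correlation(cfg)
    chol = np.linalg.cholesky(R) * cfg.innovation_sd

    p_pos = rng.normal(0.0, cfg.person_trait_sd, size=n_persons)
    p_neg = rng.normal(0.0, cfg.person_trait_sd, size=n_persons)
    neg = cfg.valence_codes()
    person_effect = np.where(neg[None, :] == 1.0, p_neg[:, None], p_pos[:, None])
    m = np.asarray(cfg.item_trait_means)[None, :] + person_effect  # (n, k)

    phi = cfg.ar_coef
    stat_scale = 1.0 / math.sqrt(1.0 - phi**2)
    e = np.empty((n_persons, k, T))
    z = rng.standard_normal((n_persons, T, k))
    e[:, :, 0] = (z[:, 0] @ chol.T) * stat_scale
    for t in range(1, T):
        e[:, :, t] = phi * e[:, :, t - 1] + z[:, t] @ chol.T
    x = m[:, :, None] + e
    u = np.clip(x, 0.0, 1.0) if censor else x
    return u, p_pos, p_neg


def _beta_missing_rates(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    mu, kappa = cfg.missing_rate_mean, cfg.missing_rate_concentration
    if mu <= 0:
        return np.zeros(n)
    if not np.isfinite(kappa):
        return np.full(n, mu)
    return rng.beta(mu * kappa, (1 - mu) * kappa, size=n)


def generate_study(cfg: SyntheticConfig | None = None, seed: int | None = None) -> StudyDataset:
    """Generate one two-arm study, fully reproducible from the seed.

    The Likert arm is, by default, a thresholded read-out of the same kind
    of VAS-granularity experience as the VAS arm (mechanism
    ``threshold_only``) — the ground-truth condition under which the
    thresholding counterfactual should explain the whole scale difference.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    frames = []
    factors = {}

    for group, n in (("likert", cfg.n_likert), ("vas", cfg.n_vas)):
        u, p_pos, p_neg = simulate_latent(cfg, n, rng)
        vas_granular = np.round(100.0 * u) / 100.0  # integer 0..100 read-out
        if group == "vas":
            raw = np.round(100.0 * u)  # raw integer response
            norm = raw / 100.0
        else:
            experience = vas_granular
            if cfg.likert_mechanism == "threshold_plus_zero_attraction":
                experience = np.where(experience < cfg.zero_attraction_cut, 0.0, experience)
            cat, norm = vas_to_likert(experience, cfg.threshold_map)
            raw = cat  # raw integer category 1..7

        rates = _beta_missing_rates(cfg, n, rng)
        observed = rng.random((n, cfg.t_max)) >= rates[:, None]
        durations = rng.lognormal(cfg.duration_log_mean, cfg.duration_log_sd, size=(n, cfg.t_max))

        pids = [f"{group[0].upper()}{i + 1:03d}" for i in range(n)]
        for i, pid in enumerate(pids):
            factors[pid] = (p_pos[i], p_neg[i])
        pidx, iidx, tidx = np.where(observed[:, None, :] & np.ones((1, len(cfg.items), 1), bool))
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.array(pids)[pidx],
                    "group": group,
                    "item": np.array([it.name for it in cfg.items])[iidx],
                    "beep": tidx + 1,
                    "value": raw[pidx, iidx, tidx].astype(int),
                    "value_norm": norm[pidx, iidx, tidx],
                    "duration_s": durations[pidx, tidx],
                }
            )
        )

    records = pd.concat(frames, ignore_index=True)

    # criterion scores load on the negative-minus-positive person factor
    all_pids = list(factors)
    contrast = np.array([factors[p][1] - factors[p][0] for p in all_pids])
    zc = (contrast - contrast.mean()) / contrast.std(ddof=0)
    crit = {}
    for col in CRITERION_COLUMNS:
        crit[col] = cfg.criterion_loading * zc + rng.standard_normal(len(all_pids))
    criteria = pd.DataFrame(crit, index=pd.Index(all_pids, name="participant_id"))

    return StudyDataset(records, cfg.items, criteria)


def config_to_dict(cfg: SyntheticConfig) -> dict:
    """Plain-dict view of a config (for YAML sidecars of true parameters)."""
    d = asdict(cfg)
    d["items"] = [{"name": it.name, "valence": it.valence} for it in cfg.items]
    d["threshold_map"] = list(cfg.threshold_map.cuts)
    d["item_trait_means"] = list(cfg.item_trait_means)
    return d
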
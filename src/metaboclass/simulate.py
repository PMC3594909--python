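"""Synthetic two-group metabolomic feature tables with known ground truth.

The clinical urine GC-MS dataset this package's evaluation suite was designed
around (65 healthy / 67 preoperative / 63 postoperative colorectal-cancer
samples, 187 peak-area variables of which 35 are identified metabolites) is
not publicly deposited, so every downstream stage is exercised on simulated
tables instead.

Generative model
----------------
Latent per-sample vectors are multivariate Gaussian with unit variances and a
block-diagonal equicorrelation structure: consecutive blocks of
``block_size`` variables share pairwise correlation ``block_rho``. The first
``n_informative`` variables receive an additive mean shift of ``effect_size``
latent standard deviations in group 1 (so ``effect_size`` is Cohen's d on the
latent scale), with alternating sign: disease signatures contain both
elevated and depleted metabolites, and the sign balance keeps the simulated
group effect from being confounded with each sample's total intensity when
tables are later row-normalised. Latent values are added to a per-variable
log-abundance baseline and exponentiated, yielding strictly positive,
right-skewed "peak areas". This mimics the positivity and skew of real peak
tables without claiming the (unknown) distribution of the study data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .tables import FeatureTable

__all__ = ["SimConfig", "generate_dataset", "generate_three_group", "assemble_case"]

#: Range of per-variable baseline log-abundances (natural log of peak area).
_LOG_BASELINE = (2.0, 6.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-group generator.

    Defaults mirror the study design being emulated: 65 vs 67 samples,
    187 variables of which 35 are flagged as identified metabolites.
    """

    n_group0: int = 65
    n_group1: int = 67
    p: int = 187
    n_informative: int = 20
    effect_size: float = 1.0
    block_size: int = 10
    block_rho: float = 0.5
    n_identified: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group0", "n_group1", "p", "block_size"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_informative < 0:
            raise ValidationError(f"n_informative must be >= 0, got {self.n_informative}")
        if self.n_identified < 1:
            raise ValidationError(f"n_identified must be >= 1, got {self.n_identified}")
        if self.n_informative > self.p:
            raise ValidationError(
                f"n_informative ({self.n_informative}) exceeds p ({self.p})"
            )
        if self.n_identified > self.p:
            raise ValidationError(f"n_identified ({self.n_identified}) exceeds p ({self.p})")
        if self.effect_size < 0:
            raise ValidationError(f"effect_size must be >= 0, got {self.effect_size}")
        if not 0 <= self.block_rho < 1:
            raise ValidationError(f"block_rho must lie in [0, 1), got {self.block_rho}")


def _latent_matrix(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Correlated standard-normal latents: equicorrelated blocks of block_size."""
    z = np.empty((n, cfg.p))
    r = cfg.block_rho
    for start in range(0, cfg.p, cfg.block_size):
        width = min(cfg.block_size, cfg.p - start)
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, width))
        z[:, start : start + width] = np.sqrt(r) * shared + np.sqrt(1.0 - r) * noise
    return z


def _ids(prefix: str, count: int) -> np.ndarray:
    width = max(3, len(str(count)))
    return np.asarray([f"{prefix}{i + 1:0{width}d}" for i in range(count)], dtype=object)


def _effect_signs(n_informative: int) -> np.ndarray:
    """Alternating +1/-1: informative metabolites rise and fall in equal measure."""
    signs = np.ones(n_informative)
    signs[1::2] = -1.0
    return signs


def generate_dataset(config: SimConfig) -> FeatureTable:
    """Draw one two-group feature table; bit-identical for a fixed seed.

    Group 0 occupies the first ``n_group0`` rows. The informative variables
    are the first ``n_informative`` columns (recorded in ``truth``), the
    identified metabolites the first ``n_identified`` (``identified_mask``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_group0 + cfg.n_group1
    baseline = rng.uniform(*_LOG_BASELINE, size=cfg.p)
    z = _latent_matrix(rng, n, cfg)
    groups = np.asarray(["0"] * cfg.n_group0 + ["1"] * cfg.n_group1, dtype=object)
    if cfg.n_informative:
        z[groups == "1", : cfg.n_informative] += cfg.effect_size * _effect_signs(
            cfg.n_informative
        )
    values = np.exp(baseline + z)
    truth = np.zeros(cfg.p, dtype=bool)
    truth[: cfg.n_informative] = True
    identified = np.zeros(cfg.p, dtype=bool)
    identified[: cfg.n_identified] = True
    return FeatureTable(
        values=values,
        sample_ids=_ids("S", n),
        variable_ids=_ids("V", cfg.p),
        groups=groups,
        identified_mask=identified,
        truth=truth,
        group_levels=("0", "1"),
    )


def generate_three_group(
    config: SimConfig | None = None,
    n_post: int = 63,
    post_effect: float | None = None,
    group_names: tuple[str, str, str] = ("normal", "preop", "postop"),
) -> FeatureTable:
    """Three-group table (baseline / disease / post-treatment) from one latent draw.

    Composes two binary designs sharing the baseline group: the disease group
    is shifted by ``config.effect_size`` on the informative variables and the
    post-treatment group by ``post_effect`` (default half the disease shift,
    emulating partial metabolic normalisation after surgery). Default sizes
    are 65 / 67 / 63 for a 195-sample table.
    """
    cfg = config or SimConfig()
    if n_post < 1:
        raise ValidationError(f"n_post must be >= 1, got {n_post}")
    if post_effect is None:
        post_effect = cfg.effect_size / 2.0
    if post_effect < 0:
        raise ValidationError(f"post_effect must be >= 0, got {post_effect}")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_group0 + cfg.n_group1 + n_post
    baseline = rng.uniform(*_LOG_BASELINE, size=cfg.p)
    z = _latent_matrix(rng, n, cfg)
    groups = np.asarray(
        [group_names[0]] * cfg.n_group0
        + [group_names[1]] * cfg.n_group1
        + [group_names[2]] * n_post,
        dtype=object,
    )
    if cfg.n_informative:
        signs = _effect_signs(cfg.n_informative)
        z[groups == group_names[1], : cfg.n_informative] += cfg.effect_size * signs
        z[groups == group_names[2], : cfg.n_informative] += post_effect * signs
    values = np.exp(baseline + z)
    truth = np.zeros(cfg.p, dtype=bool)
    truth[: cfg.n_informative] = True
    identified = np.zeros(cfg.p, dtype=bool)
    identified[: cfg.n_identified] = True
    return FeatureTable(
        values=values,
        sample_ids=_ids("S", n),
        variable_ids=_ids("V", cfg.p),
        groups=groups,
        identified_mask=identified,
        truth=truth,
    )


def assemble_case(table_full: FeatureTable, groups: tuple[str, str]) -> FeatureTable:
    """Restrict a multi-group table to a two-group analysis case.

    Rows keep their original order; labels are recoded so the first named
    group becomes 0 and the second becomes 1.
    """
    a, b = groups
    if a == b:
        raise ValidationError(f"analysis case needs two distinct groups, got {a!r} twice")
    present = set(table_full.groups)
    for g in (a, b):
        if g not in present:
            raise ValidationError(f"group {g!r} not present in table")
    mask = (table_full.groups == a) | (table_full.groups == b)
    sub = table_full.select_samples(mask)
    return sub.replace(group_levels=(a, b))
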
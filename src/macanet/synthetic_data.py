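"""Synthetic troop generator.

No public interaction matrices exist for the motivating system (a
semi-free-ranging Barbary macaque group of 52 individuals), so every
stage of the pipeline is exercised on simulated troops whose
statistical structure mirrors what the analysis assumes:

* a troop of ~52 individuals (~25 females / ~27 males), ages 1-25;
* matrilines of unequal size; a few individuals (mostly males) have no
  *observed* matriline, although the generator always knows the truth;
* a latent dominance order built from matrilineal rank inheritance
  (higher matriline -> higher base rank) with youngest ascendancy among
  sisters, and an independent stratum for males;
* dyadic interaction counts drawn independently as
  ``count_ij ~ Poisson(lambda_ij)`` with a log-linear rate carrying the
  planted gender / age / matriline / rank effects and homophily terms.

The log-rate for the ordered dyad (i gives, j receives) is::

    log lam_ij = beta0[behavior]
               - beta_age_homophily * |a_i - a_j|            (a = age rescaled to 0..1)
               + beta_matriline_homophily * 1[same true matriline]
               - beta_age_decline * (a_i + a_j) / 2
               + [grooming]  beta_gender_groom * 1[i female and j female]
               + [grooming]  beta_rank_grooming_in_female * r_j * 1[j female]
               + [agonistic] beta_gender_homophily_agonistic * 1[same gender]
               + [agonistic] beta_rank_agonism_out * r_i
               - [agonistic] beta_rank_agonism_in  * r_j
               + [agonistic] beta_matriline_centrality * m_i

where ``r`` is the latent dominance rank and ``m`` the true matriline
code, both rescaled to 0..1.  With every effect at zero the model is a
homogeneous Poisson network.  Latent ranks are returned separately and
never written into the attribute table used for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import presets
from ._seeding import derive_seed
from .errors import ConfigError
from .io_core import AttributeTable, InteractionMatrix

_LAMBDA_GUARD = 1e6


@dataclass
class GeneratorConfig:
    """Troop composition and planted effect sizes.

    Composition defaults follow the study group: 52 individuals,
    25 females, ages 1-25 years, 8 matrilines, and 9 individuals (8
    males, 1 female) whose matriline is masked as missing in the
    emitted attribute table.  Effect-size defaults are the frozen
    :data:`macanet.presets.FIELD_STUDY` preset.
    """

    n: int = 52
    n_female: int = 25
    age_min: int = 1
    age_max: int = 25
    n_matrilines: int = 8
    n_unassigned_male: int = 8
    n_unassigned_female: int = 1

    # width of the youngest-ascendancy band above each matriline base;
    # > 1 lets adjacent matrilines interleave in the dominance order
    matriline_spread: float = 4.5

    beta0_agonistic: float = presets.FIELD_STUDY["beta0_agonistic"]
    beta0_grooming: float = presets.FIELD_STUDY["beta0_grooming"]
    beta_gender_groom: float = presets.FIELD_STUDY["beta_gender_groom"]
    beta_gender_homophily_agonistic: float = presets.FIELD_STUDY["beta_gender_homophily_agonistic"]
    beta_age_homophily: float = presets.FIELD_STUDY["beta_age_homophily"]
    beta_matriline_homophily: float = presets.FIELD_STUDY["beta_matriline_homophily"]
    beta_rank_agonism_out: float = presets.FIELD_STUDY["beta_rank_agonism_out"]
    beta_rank_agonism_in: float = presets.FIELD_STUDY["beta_rank_agonism_in"]
    beta_rank_grooming_in_female: float = presets.FIELD_STUDY["beta_rank_grooming_in_female"]
    beta_age_decline: float = presets.FIELD_STUDY["beta_age_decline"]
    beta_matriline_centrality: float = presets.FIELD_STUDY["beta_matriline_centrality"]

    # Gamma-Poisson overdispersion shape; None = pure Poisson.  Present
    # as an extension hook only: no dispersion estimate exists to tune
    # it against, so the default stays Poisson.
    dispersion: float | None = None

    preset_version: str = presets.PRESET_VERSION

    def __post_init__(self) -> None:
        if not (0 < self.n_female <= self.n):
            raise ConfigError("need 0 < n_female <= n")
        if self.age_min <= 0 or self.age_max < self.age_min:
            raise ConfigError("need 0 < age_min <= age_max")
        if self.n_matrilines > self.n_female / 2:
            raise ConfigError(
                "n_matrilines too large: each matriline needs at least 2 females"
            )
        if self.n_unassigned_female > self.n_female:
            raise ConfigError("more unassigned females than females")
        if self.n_unassigned_male > self.n - self.n_female:
            raise ConfigError("more unassigned males than males")
        for name, value in self.effects().items():
            if not np.isfinite(value):
                raise ConfigError(f"effect {name} must be finite")

    def effects(self) -> dict[str, float]:
        return {k: v for k, v in asdict(self).items() if k.startswith("beta")}

    @classmethod
    def field_study(cls, **overrides) -> "GeneratorConfig":
        return cls(**overrides)

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """All planted effects zero; baselines kept (type-I calibration)."""
        zeroed = {k: 0.0 for k in presets.FIELD_STUDY if k.startswith("beta_")}
        zeroed.update(overrides)
        return cls(**zeroed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _partition_females(n_female: int, n_matrilines: int, rng: np.random.Generator) -> np.ndarray:
    """Random matriline sizes, each >= 2, summing to n_female."""
    sizes = np.full(n_matrilines, 2, dtype=int)
    extra = n_female - 2 * n_matrilines
    if extra > 0:
        sizes += rng.multinomial(extra, np.full(n_matrilines, 1.0 / n_matrilines))
    return sizes


def generate_attributes(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[AttributeTable, pd.DataFrame]:
    """Generate the troop roster.

    Returns the observable :class:`AttributeTable` (matriline masked for
    the unassigned individuals, hierarchy column empty) and a latent
    DataFrame with columns ``latent_rank`` (dominance score, larger =
    more dominant) and ``matriline`` (the true code for everyone).
    """
    rng = np.random.default_rng(seed)
    n_male = cfg.n - cfg.n_female
    ids = [f"f{k + 1:02d}" for k in range(cfg.n_female)] + [
        f"m{k + 1:02d}" for k in range(n_male)
    ]
    gender = np.array(["F"] * cfg.n_female + ["M"] * n_male)
    age = rng.integers(cfg.age_min, cfg.age_max + 1, cfg.n).astype(float)

    # matrilineal structure: females partitioned, males attached to a
    # (their mother's) matriline; codes 1..K with larger = higher-ranking
    sizes = _partition_females(cfg.n_female, cfg.n_matrilines, rng)
    fem_codes = np.repeat(np.arange(1, cfg.n_matrilines + 1), sizes)
    rng.shuffle(fem_codes)
    male_codes = rng.integers(1, cfg.n_matrilines + 1, n_male)
    true_matriline = np.concatenate([fem_codes, male_codes]).astype(float)

    # latent dominance: matriline base + youngest-ascendancy band among
    # sisters (younger sister -> higher score), and an independent
    # uniform stratum for males over the same score range
    latent = np.empty(cfg.n)
    for code in range(1, cfg.n_matrilines + 1):
        members = np.where((gender == "F") & (true_matriline == code))[0]
        # youngest first; random tie-break keeps age ties unbiased
        order = members[np.lexsort((rng.random(members.size), age[members]))]
        mcount = order.size
        frac = (mcount - np.arange(mcount)) / (mcount + 1)
        latent[order] = code + cfg.matriline_spread * frac
    male_idx = np.where(gender == "M")[0]
    latent[male_idx] = rng.uniform(1.0, cfg.n_matrilines + cfg.matriline_spread, male_idx.size)

    observed_matriline = true_matriline.copy()
    fem_mask_idx = rng.choice(np.where(gender == "F")[0], cfg.n_unassigned_female, replace=False)
    male_mask_idx = rng.choice(male_idx, cfg.n_unassigned_male, replace=False)
    observed_matriline[np.concatenate([fem_mask_idx, male_mask_idx])] = np.nan

    attrs = AttributeTable(
        pd.DataFrame(
            {
                "gender": gender,
                "age": age,
                "matriline": observed_matriline,
                "hierarchy": np.nan,
            },
            index=pd.Index(ids, name="id"),
        )
    )
    latent_df = pd.DataFrame(
        {"latent_rank": latent, "matriline": true_matriline},
        index=pd.Index(ids, name="id"),
    )
    return attrs, latent_df


def _log_rate_matrix(
    attrs: AttributeTable, latent: pd.DataFrame, cfg: GeneratorConfig, behavior: str
) -> np.ndarray:
    if behavior not in ("agonistic", "allogrooming"):
        raise ConfigError(f"unknown behavior {behavior!r}")
    gender = (attrs["gender"] == "F").to_numpy(dtype=float)  # 1 = F
    age = attrs["age"].to_numpy(dtype=float)
    span = max(cfg.age_max - cfg.age_min, 1)
    a = (age - cfg.age_min) / span
    mat = latent["matriline"].to_numpy(dtype=float)
    mat01 = (mat - 1.0) / max(cfg.n_matrilines - 1, 1)
    # ordinal latent ranks rescaled to 0..1 (uniformly spaced)
    r01 = (pd.Series(latent["latent_rank"].to_numpy()).rank().to_numpy() - 1.0) / max(
        cfg.n - 1, 1
    )

    same_mat = (mat[:, None] == mat[None, :]).astype(float)
    same_gender = (gender[:, None] == gender[None, :]).astype(float)
    both_f = np.outer(gender, gender)
    age_dist = np.abs(a[:, None] - a[None, :])

    e = np.zeros((cfg.n, cfg.n))
    e -= cfg.beta_age_homophily * age_dist
    e += cfg.beta_matriline_homophily * same_mat
    e -= cfg.beta_age_decline * (a[:, None] + a[None, :]) / 2.0
    if behavior == "allogrooming":
        e += cfg.beta0_grooming
        e += cfg.beta_gender_groom * both_f
        e += cfg.beta_rank_grooming_in_female * (r01 * gender)[None, :]
    else:
        e += cfg.beta0_agonistic
        e += cfg.beta_gender_homophily_agonistic * same_gender
        e += cfg.beta_rank_agonism_out * r01[:, None]
        e -= cfg.beta_rank_agonism_in * r01[None, :]
        e += cfg.beta_matriline_centrality * mat01[:, None]
    return e


def generate_interaction_counts(
    attrs: AttributeTable,
    latent: pd.DataFrame,
    cfg: GeneratorConfig,
    behavior: str,
    seed: int | None = None,
) -> InteractionMatrix:
    """Draw one behavior's count matrix from the log-linear rate model."""
    rng = np.random.default_rng(seed)
    lam = np.exp(_log_rate_matrix(attrs, latent, cfg, behavior))
    if np.any(lam > _LAMBDA_GUARD):
        i, j = np.unravel_index(int(np.argmax(lam)), lam.shape)
        raise ConfigError(
            f"rate overflow for dyad ({attrs.ids[i]}, {attrs.ids[j]}): "
            f"lambda={lam[i, j]:.3g} exceeds {_LAMBDA_GUARD:.0e}"
        )
    np.fill_diagonal(lam, 0.0)
    if cfg.dispersion is None:
        counts = rng.poisson(lam)
    else:
        # Gamma-Poisson mixture with shape theta: mean lam, var lam(1 + lam/theta)
        theta = float(cfg.dispersion)
        counts = rng.poisson(lam * rng.gamma(theta, 1.0 / theta, lam.shape))
    np.fill_diagonal(counts, 0)
    label = "allogrooming" if behavior == "allogrooming" else "agonistic"
    return InteractionMatrix(attrs.ids, counts, label)


def generate_dataset(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[AttributeTable, InteractionMatrix, InteractionMatrix, pd.DataFrame]:
    """One full troop: attributes, agonistic and grooming matrices, latent."""
    s_attr = derive_seed(seed, "attrs") if seed is not None else None
    s_ago = derive_seed(seed, "agonistic") if seed is not None else None
    s_gro = derive_seed(seed, "grooming") if seed is not None else None
    attrs, latent = generate_attributes(cfg, s_attr)
    agonistic = generate_interaction_counts(attrs, latent, cfg, "agonistic", s_ago)
    grooming = generate_interaction_counts(attrs, latent, cfg, "allogrooming", s_gro)
    return attrs, agonistic, grooming, latent


def generate_null_dataset(
    cfg: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[AttributeTable, InteractionMatrix, InteractionMatrix]:
    """A troop with every planted effect forced to zero (calibration)."""
    base = cfg if cfg is not None else GeneratorConfig()
    null_cfg = GeneratorConfig.null(
        n=base.n,
        n_female=base.n_female,
        age_min=base.age_min,
        age_max=base.age_max,
        n_matrilines=base.n_matrilines,
        n_unassigned_male=base.n_unassigned_male,
        n_unassigned_female=base.n_unassigned_female,
        beta0_agonistic=base.beta0_agonistic,
        beta0_grooming=base.beta0_grooming,
        dispersion=base.dispersion,
    )
    attrs, agonistic, grooming, _ = generate_dataset(null_cfg, seed)
    return attrs, agonistic, grooming
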
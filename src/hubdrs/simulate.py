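"""Synthetic cohorts of source-space ROI time series with planted effects.

The generator emulates broadband source-localized MEG signals after
pre-processing and parcellation: one stationary zero-mean time series per
cortical region, sampled at 600 Hz, with a hub-structured correlation
pattern.  Each hemisphere carries a shared latent factor; a weaker global
factor couples the hemispheres; hub regions load more strongly on their
hemispheric factor than non-hubs, which makes them the high-strength nodes
of the network:

    x_i(t) = lambda_i * g_{H(i)}(t) + mu * c(t) + sigma * eps_i(t)

with g_L, g_R, c and eps_i independent unit-variance white Gaussian
processes.  Factor loadings are scaled by ``1 + duration_slope *
log10(duration_years)`` so that longer-standing epilepsy yields higher mean
connectivity.  Because the model is a factor model, the population
covariance is valid (positive semidefinite) by construction and every
pairwise correlation has a closed form, which the tests use as an oracle
(:func:`population_correlation`).

Two planted effects tie the cohort together:

* outcome -- resections in seizure-free (ILAE1) subjects cover a larger
  expected fraction of the hub nodes than in not-seizure-free subjects;
* duration -- the multiplicative loading scale makes mean functional
  connectivity increase monotonically with log10 duration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .atlas import HEMISPHERES, RegionAtlas, build_atlas

OUTCOME_SEIZURE_FREE = "ILAE1"
OUTCOME_NOT_SEIZURE_FREE = "ILAE_gt1"
OUTCOMES = (OUTCOME_SEIZURE_FREE, OUTCOME_NOT_SEIZURE_FREE)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Group sizes default to a 31-subject cohort with 12 seizure-free
    subjects.  Signals default to one minute at 600 Hz.  Factor loadings
    (hub 0.9, base 0.4, global 0.2, noise SD 1.0) give hub nodes a clearly
    larger intra-hemispheric strength than non-hubs while keeping all
    pairwise correlations well below 1; hub-hit fractions 0.9 / 0.1 plant a
    strong outcome effect; ``duration_slope`` = 0.05 per decade of duration
    plants a weak positive duration--connectivity association.
    """

    n_subjects: int = 31
    n_seizure_free: int = 12
    n_regions: int = 32
    fs: float = 600.0
    record_minutes: float = 1.0
    n_hubs_per_hemisphere: int = 4
    loading_hub: float = 0.9
    loading_base: float = 0.4
    loading_global: float = 0.2
    noise_sd: float = 1.0
    hub_hit_fraction_good: float = 0.9
    hub_hit_fraction_poor: float = 0.1
    resection_size: int = 6
    duration_range_years: tuple[float, float] = (2.0, 40.0)
    duration_slope: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        # equality is allowed: it is the null configuration with no planted
        # outcome effect
        if not (0 <= self.hub_hit_fraction_poor <= self.hub_hit_fraction_good <= 1):
            raise ValueError(
                "require 0 <= hub_hit_fraction_poor <= hub_hit_fraction_good <= 1"
            )
        if self.resection_size < 1:
            raise ValueError("resection_size must be >= 1")
        for name in ("loading_hub", "loading_base", "loading_global"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.duration_range_years
        if not (0 < lo <= hi):
            raise ValueError("duration range must satisfy 0 < min <= max")
        if not (0 < self.n_seizure_free <= self.n_subjects):
            raise ValueError("need 0 < n_seizure_free <= n_subjects")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_hubs_per_hemisphere < 1:
            raise ValueError("n_hubs_per_hemisphere must be >= 1")
        if self.n_regions < 4 or self.n_regions % 2:
            raise ValueError("n_regions must be even and >= 4")
        if self.n_hubs_per_hemisphere > self.n_regions // 2:
            raise ValueError("more hubs than regions in a hemisphere")
        if self.fs <= 0 or self.record_minutes <= 0:
            raise ValueError("fs and record_minutes must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.record_minutes * 60.0 * self.fs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["duration_range_years"] = list(self.duration_range_years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "duration_range_years" in d:
            d["duration_range_years"] = tuple(d["duration_range_years"])
        return cls(**d)


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth record used by recovery tests."""

    hub_region_ids: frozenset[int]
    planted_mean_fc: float


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    atlas: RegionAtlas
    timeseries: np.ndarray  # (n_regions, n_samples)
    fs: float
    removed_regions: frozenset[int]
    outcome: str
    duration_years: float
    truth: SubjectTruth

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be in {OUTCOMES}")
        if not self.removed_regions:
            raise ValueError("removed_regions must be nonempty")
        hemis = {self.atlas.hemisphere_of(r) for r in self.removed_regions}
        if len(hemis) != 1:
            raise ValueError("resection must lie within a single hemisphere")


def _loadings(
    atlas: RegionAtlas,
    config: CohortConfig,
    hub_ids: Sequence[int],
    duration_years: float,
) -> tuple[np.ndarray, float, float]:
    """Per-region hemispheric-factor loadings, global loading and scale."""
    hub_ids = frozenset(int(h) for h in hub_ids)
    unknown = hub_ids - set(atlas.region_ids.tolist())
    if unknown:
        raise ValueError(f"hub ids not in atlas: {sorted(unknown)}")
    if duration_years <= 0:
        raise ValueError("duration_years must be > 0")
    scale = 1.0 + config.duration_slope * np.log10(duration_years)
    is_hub = np.isin(atlas.region_ids, sorted(hub_ids))
    lam = scale * np.where(is_hub, config.loading_hub, config.loading_base)
    mu = scale * config.loading_global
    return lam, mu, scale


def simulate_subject_timeseries(
    atlas: RegionAtlas,
    config: CohortConfig,
    hub_ids: Sequence[int],
    duration_years: float,
    seed: int,
) -> np.ndarray:
    """Simulate one subject's (n_regions x n_samples) ROI signal matrix.

    Deterministic given ``seed``.  Durations must fall within the config's
    duration range so that the planted loading scale stays in its intended
    band.
    """
    lo, hi = config.duration_range_years
    if not (lo <= duration_years <= hi):
        raise ValueError(
            f"duration {duration_years} outside configured range [{lo}, {hi}]"
        )
    lam, mu, _ = _loadings(atlas, config, hub_ids, duration_years)
    n = atlas.n_regions
    t = config.n_samples
    rng = np.random.default_rng(seed)
    g = {h: rng.standard_normal(t) for h in HEMISPHERES}
    c = rng.standard_normal(t)
    eps = rng.standard_normal((n, t))
    hemi = atlas.hemispheres
    shared = np.where(hemi[:, None] == "L", g["L"][None, :], g["R"][None, :])
    return lam[:, None] * shared + mu * c[None, :] + config.noise_sd * eps


def population_correlation(
    atlas: RegionAtlas,
    config: CohortConfig,
    hub_ids: Sequence[int],
    duration_years: float,
) -> np.ndarray:
    """Closed-form population correlation matrix of the factor model.

    cov(x_i, x_j) = lambda_i lambda_j [same hemisphere] + mu^2 (i != j);
    var(x_i) = lambda_i^2 + mu^2 + sigma^2.
    """
    lam, mu, _ = _loadings(atlas, config, hub_ids, duration_years)
    hemi = atlas.hemispheres
    same = hemi[:, None] == hemi[None, :]
    cov = np.where(same, np.outer(lam, lam), 0.0) + mu**2
    var = lam**2 + mu**2 + config.noise_sd**2
    corr = cov / np.sqrt(np.outer(var, var))
    np.fill_diagonal(corr, 1.0)
    return corr


def planted_mean_fc(
    atlas: RegionAtlas,
    config: CohortConfig,
    hub_ids: Sequence[int],
    duration_years: float,
) -> float:
    """Population mean of all off-diagonal correlations (mean-FC truth)."""
    corr = population_correlation(atlas, config, hub_ids, duration_years)
    iu = np.triu_indices(atlas.n_regions, k=1)
    return float(corr[iu].mean())


def plant_resection(
    atlas: RegionAtlas,
    hub_ids: Sequence[int],
    outcome: str,
    config: CohortConfig,
    seed: int,
) -> frozenset[int]:
    """Draw a unilateral resection with an outcome-dependent hub overlap.

    ``hub_ids`` are the hub regions of the epileptogenic hemisphere; the
    resection is drawn in that hemisphere.  Each hub is included
    independently with probability ``hub_hit_fraction_good`` (ILAE1) or
    ``hub_hit_fraction_poor`` (otherwise), so the expected fraction of hubs
    inside the resection equals the configured hit fraction; the remaining
    slots are filled with uniformly chosen non-hub regions of the same
    hemisphere.  Requires ``resection_size`` to be at least the number of
    hubs whenever the hit probability is positive, so the Bernoulli draws
    always fit.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be in {OUTCOMES}")
    hub_ids = sorted(int(h) for h in hub_ids)
    if not hub_ids:
        raise ValueError("hub_ids must be nonempty")
    hemis = {atlas.hemisphere_of(h) for h in hub_ids}
    if len(hemis) != 1:
        raise ValueError("hub_ids must lie within a single hemisphere")
    hemi = hemis.pop()
    hemi_ids = atlas.region_ids[atlas.hemisphere_mask(hemi)]
    if config.resection_size > hemi_ids.size:
        raise ValueError(
            f"resection_size {config.resection_size} exceeds hemisphere size "
            f"{hemi_ids.size}"
        )
    p = (
        config.hub_hit_fraction_good
        if outcome == OUTCOME_SEIZURE_FREE
        else config.hub_hit_fraction_poor
    )
    if p > 0 and config.resection_size < len(hub_ids):
        raise ValueError(
            "resection_size must be >= number of hubs per hemisphere when the "
            "hub hit fraction is positive"
        )
    non_hubs = np.setdiff1d(hemi_ids, hub_ids)
    if p < 1 and config.resection_size > non_hubs.size:
        # a zero-hit draw would need more non-hub fillers than exist
        raise ValueError(
            "resection_size must not exceed the number of non-hub regions in "
            "the hemisphere unless every hub is hit with certainty"
        )
    rng = np.random.default_rng(seed)
    hits = [h for h in hub_ids if rng.random() < p]
    n_fill = config.resection_size - len(hits)
    fill = rng.choice(non_hubs, size=n_fill, replace=False) if n_fill else []
    return frozenset(int(r) for r in list(hits) + list(fill))


def sample_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw a full cohort; reproducible from ``config.seed``.

    A master seed sequence spawns one substream per subject (plus one
    cohort-level stream for outcome assignment), so subjects are mutually
    independent and the cohort is reproducible as a whole.
    """
    atlas = build_atlas(config.n_regions)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects + 1)
    cohort_rng = np.random.default_rng(children[0])

    order = cohort_rng.permutation(config.n_subjects)
    seizure_free = set(order[: config.n_seizure_free].tolist())
    lo, hi = config.duration_range_years
    durations = 10.0 ** cohort_rng.uniform(
        np.log10(lo), np.log10(hi), size=config.n_subjects
    )

    half = config.n_regions // 2
    records: list[SubjectRecord] = []
    for i in range(config.n_subjects):
        sub_rng = np.random.default_rng(children[i + 1])
        # integer sub-seeds (< 2**31) for the two seed-taking components
        ts_seed, resec_seed = (
            int(s) for s in children[i + 1].generate_state(2) % (2**31)
        )
        hubs_l = sub_rng.choice(
            atlas.region_ids[:half], size=config.n_hubs_per_hemisphere, replace=False
        )
        hubs_r = sub_rng.choice(
            atlas.region_ids[half:], size=config.n_hubs_per_hemisphere, replace=False
        )
        resect_hemi = "L" if sub_rng.random() < 0.5 else "R"
        outcome = (
            OUTCOME_SEIZURE_FREE if i in seizure_free else OUTCOME_NOT_SEIZURE_FREE
        )
        all_hubs = np.concatenate([hubs_l, hubs_r])
        removed = plant_resection(
            atlas,
            hubs_l if resect_hemi == "L" else hubs_r,
            outcome,
            config,
            seed=resec_seed,
        )
        ts = simulate_subject_timeseries(
            atlas, config, all_hubs, durations[i], seed=ts_seed
        )
        truth = SubjectTruth(
            hub_region_ids=frozenset(int(h) for h in all_hubs),
            planted_mean_fc=planted_mean_fc(atlas, config, all_hubs, durations[i]),
        )
        records.append(
            SubjectRecord(
                subject_id=f"sub{i + 1:03d}",
                atlas=atlas,
                timeseries=ts,
                fs=config.fs,
                removed_regions=removed,
                outcome=outcome,
                duration_years=float(durations[i]),
                truth=truth,
            )
        )
    return records


def write_cohort(records: Sequence[SubjectRecord], outdir: str | Path) -> None:
    """Write a cohort directory: atlas.tsv, per-subject ts CSV + meta JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not records:
        raise ValueError("empty cohort")
    records[0].atlas.write_tsv(outdir / "atlas.tsv")
    manifest = {"subjects": [], "n_regions": records[0].atlas.n_regions}
    for rec in records:
        np.savetxt(outdir / f"sub-{rec.subject_id}_ts.csv", rec.timeseries,
                   delimiter=",")
        meta = {
            "subject_id": rec.subject_id,
            "fs": rec.fs,
            "outcome": rec.outcome,
            "duration_years": rec.duration_years,
            "removed_regions": sorted(rec.removed_regions),
            "truth": {
                "hub_region_ids": sorted(rec.truth.hub_region_ids),
                "planted_mean_fc": rec.truth.planted_mean_fc,
            },
        }
        with open(outdir / f"sub-{rec.subject_id}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        manifest["subjects"].append(rec.subject_id)
    with open(outdir / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
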
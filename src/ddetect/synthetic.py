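"""Mixture-model census simulation and the sensitivity experiment.

Generates censuses from Gaussian mixtures on the log10 body-mass scale
with known between-mode gaps, emulating a multimodal community (ten
aggregations of similarly sized species by default).  The sensitivity
experiment varies sample size (20-100) and census success (fraction of
the community actually recorded, 0.75-1.0), runs the detector on every
simulated census, and pools the detected gap locations for model-based
clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .core_null import RankedCensus, prepare_census
from .gap_test import detect_discontinuities

__all__ = [
    "MixtureSpec",
    "SimulatedCensus",
    "SensitivityResult",
    "default_mixture",
    "simulate_census",
    "apply_census_success",
    "run_sensitivity",
    "cluster_discontinuities",
    "gap_recovery",
    "location_spread_by_true_gap",
]


@dataclass(frozen=True)
class MixtureSpec:
    """A Gaussian mixture on the log10 mass axis with known gap locations."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if means.size < 2:
            raise ValueError("a mixture with known gaps needs at least 2 modes")
        if not (np.diff(means) > 0).all():
            raise ValueError("means must be strictly increasing")
        if (sds <= 0).any():
            raise ValueError("standard deviations must be positive")
        if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "weights", weights)

    @property
    def k(self) -> int:
        return self.means.size

    @property
    def true_gap_midpoints(self) -> np.ndarray:
        """Boundaries between adjacent modes: midpoints of consecutive means."""
        return 0.5 * (self.means[:-1] + self.means[1:])

    @property
    def mode_spacing(self) -> float:
        return float(np.diff(self.means).mean())

    def density(self, x) -> np.ndarray:
        """Closed-form mixture density on the log10 axis."""
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        comp = np.exp(-0.5 * z * z) / (self.sds * np.sqrt(2 * np.pi))
        return comp @ self.weights


@dataclass(frozen=True)
class SimulatedCensus(RankedCensus):
    """A census with mixture ground truth: component index per entity."""

    components: tuple = ()


@dataclass(frozen=True)
class SensitivityResult:
    """Harvested detections plus optional pooled clustering.

    ``runs`` has one row per detection run (size, success, replicate,
    seed, h*, flag count); ``detections`` one row per flagged gap with
    its log10 midpoint and full provenance.  After clustering,
    ``detections`` gains a ``cluster`` column and ``cluster_summary``
    holds per-cluster location mean, spread and count.
    """

    runs: pd.DataFrame
    detections: pd.DataFrame
    spec: MixtureSpec
    n_clusters: int | None = None
    cluster_summary: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def default_mixture(
    k: int = 10,
    log_range: tuple[float, float] = (0.5, 5.0),
    sd_range: tuple[float, float] = (0.05, 0.12),
) -> MixtureSpec:
    """Equal-weight mixture with means and sds increasing evenly on log10.

    Defaults place k=10 modes from log10(mass)=0.5 to 5.0 — roughly
    shrew (~3 g) to moose (~100 kg) — with standard deviations growing
    linearly so larger-bodied modes are wider, and a separation-to-sd
    ratio >= 4 so all modes are resolvable in the analytic density.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    means = np.linspace(log_range[0], log_range[1], k)
    sds = np.linspace(sd_range[0], sd_range[1], k)
    weights = np.full(k, 1.0 / k)
    return MixtureSpec(means=means, sds=sds, weights=weights)


def simulate_census(spec: MixtureSpec, n: int = 100, seed: int = 0) -> SimulatedCensus:
    """Draw an n-entity census from the mixture.

    Log10 masses are drawn component-wise and exponentiated to grams;
    the census is rank-ordered with component memberships carried along
    as ground truth.
    """
    if n < 3:
        raise ValueError("census needs at least 3 entities")
    rng = np.random.default_rng(seed)
    comp = rng.choice(spec.k, size=n, p=spec.weights)
    logmass = rng.normal(spec.means[comp], spec.sds[comp])
    order = np.argsort(logmass, kind="stable")
    base = prepare_census(10.0 ** logmass, labels=[f"sim{i + 1}" for i in range(n)])
    return SimulatedCensus(
        logmass=base.logmass,
        labels=base.labels,
        components=tuple(int(c) for c in comp[order]),
    )


def apply_census_success(census: RankedCensus, success: float, seed: int = 0):
    """Randomly delete entities, keeping round(success * n) of them.

    Models incomplete census success: each entity is equally likely to
    be missed.  Ground-truth components, when present, are subset too.
    """
    if not 0.0 < success <= 1.0:
        raise ValueError("census success must be in (0, 1]")
    n_keep = int(round(success * census.n))
    if n_keep < 3:
        raise ValueError("census success leaves fewer than 3 entities")
    if n_keep == census.n:
        return census
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(census.n, size=n_keep, replace=False))
    logmass = census.logmass[keep]
    labels = tuple(census.labels[i] for i in keep)
    if isinstance(census, SimulatedCensus):
        return SimulatedCensus(
            logmass=logmass,
            labels=labels,
            components=tuple(census.components[i] for i in keep),
        )
    return RankedCensus(logmass=logmass, labels=labels)


def _flagged_midpoints(report) -> np.ndarray:
    flagged = report.flagged
    return 0.5 * (flagged["lower_logmass"].to_numpy() + flagged["upper_logmass"].to_numpy())


def gap_recovery(locations, spec: MixtureSpec, tol: float | None = None) -> float:
    """Fraction of true between-mode gaps with a detection within ``tol``.

    ``tol`` defaults to half the mode spacing: a detection counts for a
    true gap if its log10 midpoint lands within half a mode spacing of
    that gap's true midpoint.
    """
    if tol is None:
        tol = 0.5 * spec.mode_spacing
    locations = np.asarray(locations, dtype=float)
    truths = spec.true_gap_midpoints
    if locations.size == 0:
        return 0.0
    hit = np.abs(locations[:, None] - truths[None, :]).min(axis=0) <= tol
    return float(hit.mean())


def location_spread_by_true_gap(locations, spec: MixtureSpec) -> float:
    """Mean sd of detected locations around each true gap midpoint.

    Each detection is assigned to the true between-mode gap whose
    midpoint lies within half a mode spacing; gaps with fewer than two
    assigned detections contribute nothing.  This measures the precision
    of discontinuity *location* under known ground truth.
    """
    locations = np.asarray(locations, dtype=float)
    half = 0.5 * spec.mode_spacing
    sds = []
    for t in spec.true_gap_midpoints:
        sel = locations[np.abs(locations - t) <= half]
        if sel.size > 1:
            sds.append(sel.std(ddof=1))
    return float(np.mean(sds)) if sds else float("nan")


def run_sensitivity(
    spec: MixtureSpec,
    sample_sizes=(20, 30, 40, 50, 60, 70, 80, 90, 100),
    successes=(0.75, 0.8, 0.85, 0.9, 0.95, 1.0),
    replicates: int = 1000,
    threshold: float = 0.90,
    B: int = 5000,
    increment: float = 0.001,
    mode: str = "centers",
    seed: int = 0,
    cluster: bool = True,
    k_max: int | None = None,
) -> SensitivityResult:
    """Factorial sensitivity experiment: size x success x replicate.

    For every cell and replicate a fresh census is simulated at the
    cell's sample size, thinned to the cell's census success, and run
    through the detector; flagged gap midpoints are harvested with full
    provenance.  Pooled detections are optionally clustered with a 1-D
    Gaussian mixture chosen by BIC.
    """
    if replicates < 10:
        raise ValueError("need at least 10 replicates per cell")
    run_rows, det_rows = [], []
    run_id = 0
    for size in sample_sizes:
        for success in successes:
            for rep in range(replicates):
                ss = np.random.SeedSequence(entropy=seed, spawn_key=(run_id,))
                s_sim, s_thin, s_dd = (int(s % 2**31) for s in ss.generate_state(3))
                census = simulate_census(spec, n=size, seed=s_sim)
                census = apply_census_success(census, success, seed=s_thin)
                report = detect_discontinuities(
                    census,
                    threshold=threshold,
                    B=B,
                    increment=increment,
                    mode=mode,
                    seed=s_dd,
                )
                locs = _flagged_midpoints(report)
                run_rows.append(
                    {
                        "run_id": run_id,
                        "sample_size": size,
                        "census_success": success,
                        "replicate": rep,
                        "seed": s_dd,
                        "h_star": report.meta["h_star"],
                        "n_flagged": locs.size,
                        "recovery": gap_recovery(locs, spec),
                    }
                )
                det_rows.extend(
                    {
                        "run_id": run_id,
                        "sample_size": size,
                        "census_success": success,
                        "replicate": rep,
                        "seed": s_dd,
                        "location": loc,
                    }
                    for loc in locs
                )
                run_id += 1
    runs = pd.DataFrame(run_rows)
    detections = pd.DataFrame(
        det_rows,
        columns=["run_id", "sample_size", "census_success", "replicate", "seed", "location"],
    )
    n_clusters = None
    summary = None
    if cluster and len(detections) >= 10:
        labels, n_clusters, summary = cluster_discontinuities(
            detections["location"].to_numpy(), k_max=k_max or 2 * spec.k
        )
        detections = detections.assign(cluster=labels)
    meta = {
        "threshold": threshold,
        "B": B,
        "increment": increment,
        "mode": mode,
        "seed": seed,
        "replicates": replicates,
        "sample_sizes": tuple(sample_sizes),
        "successes": tuple(successes),
    }
    return SensitivityResult(
        runs=runs,
        detections=detections,
        spec=spec,
        n_clusters=n_clusters,
        cluster_summary=summary,
        meta=meta,
    )


def cluster_discontinuities(locations, k_max: int = 20):
    """Cluster pooled detections with 1-D Gaussian mixtures chosen by BIC.

    Fits equal-variance ("tied") and free-variance mixtures for 1..k_max
    components, keeps the fit minimising BIC, and assigns each location
    to its maximum-responsibility component.

    Returns ``(labels, n_clusters, summary)`` where ``summary`` has one
    row per cluster with mean location, spread (sd) and member count.
    """
    locations = np.asarray(locations, dtype=float)
    if locations.size < 10:
        raise ValueError("need at least 10 locations to cluster")
    distinct = np.unique(locations)
    if distinct.size == 1:
        labels = np.zeros(locations.size, dtype=int)
        summary = pd.DataFrame(
            {"cluster": [0], "location_mean": [distinct[0]], "location_sd": [0.0],
             "count": [locations.size]}
        )
        return labels, 1, summary
    X = locations.reshape(-1, 1)
    k_max = int(min(k_max, distinct.size))
    best = None
    best_bic = np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, k_max + 1):
            for cov in ("tied", "full"):
                gm = GaussianMixture(
                    n_components=k, covariance_type=cov, n_init=2, random_state=0,
                    reg_covar=1e-8,
                )
                try:
                    gm.fit(X)
                except Exception:
                    continue
                bic = gm.bic(X)
                if bic < best_bic:
                    best, best_bic = gm, bic
    labels = best.predict(X)
    # relabel clusters in order of increasing mean location
    order = np.argsort(best.means_.ravel())
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    labels = remap[labels]
    rows = []
    for c in np.unique(labels):
        pts = locations[labels == c]
        rows.append(
            {"cluster": int(c), "location_mean": pts.mean(),
             "location_sd": pts.std(ddof=1) if pts.size > 1 else 0.0,
             "count": pts.size}
        )
    summary = pd.DataFrame(rows)
    return labels, int(best.n_components), summary
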
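"""Virtual species: suitability, occurrence probability, presence-absence.

A virtual species is a simulated taxon whose habitat suitability (HS) is an
explicit, known function of the climate surfaces. Two niche constructions
are supported:

* **response-curve niches** — HS is the product of univariate response
  functions (sigmoids, Gaussian bells, threshold-like logistics) of named
  variables, min-max rescaled to [0, 1];
* **PCA niches** — a PCA is fitted to a random background sample of the
  (standardized) cell climate vectors, every cell is scored on the first
  two components, and HS is a product of Gaussian responses around a niche
  centre in that 2-D climate space. Broad niche breadth yields a climate
  generalist, narrow breadth a restricted species.

HS is converted to occurrence probability through the logistic

    P(occurrence) = 1 / (1 + exp((HS - beta) / alpha))

(alpha < 0: slope, smaller |alpha| = shallower; beta: inflection, P = 0.5
at HS = beta), realized into presence-absence by independent per-cell
Bernoulli draws, and finally "virtually sampled": point datasets of fixed
size, optionally restricted to a buffer around a random set of seed
presence cells, with imperfect detection turning some true presences into
false absences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit
from sklearn.decomposition import PCA

from ._rng import substream
from .grids import ClimateGrid, ClimateStack, GridSpec, OccProbMap, PresAbsMap, SuitabilityMap

__all__ = [
    "ResponseFunction",
    "PcaNiche",
    "ConversionParams",
    "PresAbsSample",
    "eval_response",
    "suitability_from_responses",
    "suitability_from_pca_niche",
    "occurrence_probability",
    "realize_presence_absence",
    "sample_presabs",
    "samples_to_csv",
    "samples_from_csv",
]

ResponseKind = Literal[
    "increasing_sigmoid", "decreasing_sigmoid", "gaussian_bell", "threshold_logistic"
]


@dataclass(frozen=True)
class ResponseFunction:
    """Univariate response curve mapping a variable to [0, 1].

    ``x0`` is the inflection (sigmoids) or mode (bell); ``s`` the scale
    (sigmoid slope scale or bell sd), in variable units. A
    ``threshold_logistic`` is a decreasing sigmoid whose small ``s`` makes
    suitability collapse shortly past ``x0``.
    """

    kind: ResponseKind
    variable_name: str
    x0: float
    s: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("response scale s must be > 0")

    def __call__(self, x):
        return eval_response(self, x)


def eval_response(fn: ResponseFunction, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    z = (x - fn.x0) / fn.s
    if fn.kind == "increasing_sigmoid":
        return expit(z)
    if fn.kind in ("decreasing_sigmoid", "threshold_logistic"):
        return expit(-z)
    if fn.kind == "gaussian_bell":
        return np.exp(-((x - fn.x0) ** 2) / (2.0 * fn.s**2))
    raise ValueError(f"unknown response kind: {fn.kind}")


@dataclass(frozen=True)
class PcaNiche:
    """Gaussian niche in the 2-D space of the first two principal components."""

    niche_center: tuple[float, float]
    niche_breadth: tuple[float, float]
    background_sample_size: int = 2000

    def __post_init__(self) -> None:
        if min(self.niche_breadth) <= 0:
            raise ValueError("niche breadth must be > 0")


@dataclass(frozen=True)
class ConversionParams:
    """Logistic suitability-to-probability conversion plus detection."""

    alpha: float = -0.05
    beta: float = 0.5
    detection_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection probability must lie in [0, 1]")


def _rescale_01(values: np.ndarray, mask: np.ndarray, context: str) -> np.ndarray:
    unmasked = values[~mask]
    lo, hi = float(unmasked.min()), float(unmasked.max())
    if hi <= lo:
        raise ValueError(
            f"cannot min-max rescale a constant suitability surface ({context}); "
            "all unmasked cells share one value"
        )
    out = (values - lo) / (hi - lo)
    return np.where(mask, 0.0, out)


def suitability_from_responses(
    stack: ClimateStack, fns: Sequence[ResponseFunction]
) -> SuitabilityMap:
    """Per-cell product of response curves, min-max rescaled over unmasked cells."""
    missing = [fn.variable_name for fn in fns if fn.variable_name not in stack]
    if missing:
        raise KeyError(f"response variables absent from stack: {missing}")
    spec = stack.spec
    prod = np.ones(spec.shape)
    for fn in fns:
        prod = prod * eval_response(fn, stack[fn.variable_name].values)
    values = _rescale_01(prod, spec.mask, "product of responses")
    return ClimateGrid(spec, values, "suitability")


def suitability_from_pca_niche(
    stack: ClimateStack, niche: PcaNiche, seed: int = 0
) -> SuitabilityMap:
    """Score cells on a background-sample PCA and apply a Gaussian niche.

    The PCA is fitted on a seeded random sample of standardized cell
    climate vectors (emulating a background-point ordination); suitability
    is the product of Gaussian responses on PC1/PC2, rescaled to [0, 1].
    """
    spec = stack.spec
    table, idx = stack.to_table()
    n_cells, p = table.shape
    if niche.background_sample_size < p:
        raise ValueError("background sample smaller than the number of variables")
    n_bg = min(niche.background_sample_size, n_cells)
    rng = substream(seed, "pca_background")
    bg_rows = rng.choice(n_cells, size=n_bg, replace=False)

    mean = table[bg_rows].mean(axis=0)
    sd = table[bg_rows].std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    std_all = (table - mean) / sd
    pca = PCA(n_components=2, random_state=0)
    pca.fit(std_all[bg_rows])
    scores = pca.transform(std_all)

    (c1, c2), (b1, b2) = niche.niche_center, niche.niche_breadth
    suit = np.exp(-((scores[:, 0] - c1) ** 2) / (2 * b1**2)) * np.exp(
        -((scores[:, 1] - c2) ** 2) / (2 * b2**2)
    )
    values = np.zeros(spec.shape).ravel()
    values[idx] = suit
    values = _rescale_01(values.reshape(spec.shape), spec.mask, "PCA niche")
    return ClimateGrid(spec, values, "suitability")


def occurrence_probability(hs: SuitabilityMap, cp: ConversionParams) -> OccProbMap:
    """Logistic conversion of suitability to occurrence probability;
    strictly increasing in HS for alpha < 0, with P = 0.5 at HS = beta."""
    spec = hs.spec
    p = expit(-(hs.values - cp.beta) / cp.alpha)
    p = np.where(spec.mask, 0.0, p)
    return ClimateGrid(spec, p, "occurrence_probability")


def realize_presence_absence(prob: OccProbMap, seed: int = 0) -> PresAbsMap:
    """Independent per-cell Bernoulli draws from the probability map."""
    values = prob.values
    if values[~prob.spec.mask].min() < 0 or values[~prob.spec.mask].max() > 1:
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    rng = substream(seed, "presence_absence")
    draws = (rng.random(prob.spec.shape) < values).astype(float)
    draws = np.where(prob.spec.mask, 0.0, draws)
    return ClimateGrid(prob.spec, draws, "presence_absence")


@dataclass
class PresAbsSample:
    """One virtual sampling replicate: labelled points plus provenance."""

    sample_id: int
    points: pd.DataFrame  # columns x, y, label
    species_tag: str = "species"
    buffer_km: float | None = None
    seed: int | None = None

    @property
    def prevalence(self) -> float:
        return float(self.points["label"].mean())


def sample_presabs(
    pa: PresAbsMap,
    strategy: Literal["whole_extent", "buffered"] = "whole_extent",
    buffer_km: float | None = None,
    n_seed_presences: int = 500,
    n_points: int = 300,
    n_samples: int = 50,
    detection: float = 1.0,
    seed: int = 0,
    species_tag: str = "species",
) -> list[PresAbsSample]:
    """Draw ``n_samples`` presence-absence point datasets from a PA map.

    ``buffered`` restricts eligibility to cells whose centre lies within
    ``buffer_km`` of any of ``n_seed_presences`` randomly chosen presence
    cells (one seeded buffer shared by all samples). Each sampled presence
    is recorded as a presence with probability ``detection`` and as a
    false absence otherwise; absences are recorded faithfully.
    """
    spec = pa.spec
    unmasked = ~spec.mask
    rows, cols = np.nonzero(unmasked)
    presence = pa.values[rows, cols] > 0.5

    if strategy == "buffered":
        if buffer_km is None or buffer_km <= 0:
            raise ValueError("buffered sampling requires a positive buffer_km")
        pres_idx = np.flatnonzero(presence)
        if pres_idx.size == 0:
            raise ValueError("buffered sampling requires at least one presence cell")
        if pres_idx.size < n_seed_presences:
            warnings.warn(
                f"only {pres_idx.size} presence cells available for "
                f"{n_seed_presences} requested buffer seeds; using all",
                stacklevel=2,
            )
            chosen = pres_idx
        else:
            rng = substream(seed, "buffer_seeds")
            chosen = rng.choice(pres_idx, size=n_seed_presences, replace=False)
        sx, sy = spec.center_of(rows[chosen], cols[chosen])
        cx, cy = spec.center_of(rows, cols)
        tree = cKDTree(np.column_stack([sx, sy]))
        dist, _ = tree.query(np.column_stack([cx, cy]), k=1)
        eligible = dist <= buffer_km
    elif strategy == "whole_extent":
        eligible = np.ones(rows.size, dtype=bool)
    else:
        raise ValueError(f"unknown strategy: {strategy}")

    elig_idx = np.flatnonzero(eligible)
    if elig_idx.size < n_points:
        raise ValueError(
            f"only {elig_idx.size} eligible cells for samples of {n_points} points"
        )

    samples = []
    for s in range(n_samples):
        rng = substream(seed, "sample", s)
        pick = rng.choice(elig_idx, size=n_points, replace=False)
        x, y = spec.center_of(rows[pick], cols[pick])
        true_label = presence[pick]
        detected = rng.random(n_points) < detection
        label = (true_label & detected).astype(int)
        df = pd.DataFrame({"x": x, "y": y, "label": label})
        samples.append(
            PresAbsSample(
                sample_id=s,
                points=df,
                species_tag=species_tag,
                buffer_km=buffer_km if strategy == "buffered" else None,
                seed=seed,
            )
        )
    return samples


def samples_to_csv(samples: Sequence[PresAbsSample], path: str | Path) -> None:
    frames = [
        s.points.assign(sample_id=s.sample_id)[["sample_id", "x", "y", "label"]]
        for s in samples
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def samples_from_csv(path: str | Path, species_tag: str = "species") -> list[PresAbsSample]:
    df = pd.read_csv(path)
    out = []
    for sid, group in df.groupby("sample_id", sort=True):
        out.append(
            PresAbsSample(
                sample_id=int(sid),
                points=group[["x", "y", "label"]].reset_index(drop=True),
                species_tag=species_tag,
            )
        )
    return out
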
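"""Population structure: AMOVA pairwise FST, PCA, geographic surfaces.

FST follows the AMOVA variance-component formulation on haplotypic
distances: with total sum of squared inter-individual distances partitioned
within/among populations, FST = sigma2_a / (sigma2_a + sigma2_w).  The
inter-haplotype distance is either 0/1 identity or the stepwise sum of
squared repeat differences over the 23 single-copy loci (an RST-like
option).  Significance is by permutation of individuals across the pair with
the (b+1)/(m+1) p-value estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import PopulationDataset




def _group_labels(ds, by: str):
    if by == "population":
        return ds.populations
    if by == "ethnicity":
        return ds.ethnicities
    raise ValueError("by must be 'population' or 'ethnicity'")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # FST point estimates, symmetric, zero diagonal
    pvalues: np.ndarray
    n_permutations: int
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def pvalue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvalues, index=self.labels, columns=self.labels)

    def clipped(self) -> np.ndarray:
        """Negative estimates clipped to 0 (display convention)."""
        return np.clip(self.values, 0.0, None)


def _amova_fst(d2: np.ndarray, sizes: Sequence[int]) -> float:
    """Phi-ST from a squared-distance matrix with samples grouped in blocks.

    ``d2`` must be ordered so the first sizes[0] rows are population 1, etc.
    """
    n_total = d2.shape[0]
    n_pops = len(sizes)
    ss_total = d2[np.triu_indices(n_total, 1)].sum() / n_total
    ss_within = 0.0
    start = 0
    for nk in sizes:
        block = d2[start : start + nk, start : start + nk]
        ss_within += block[np.triu_indices(nk, 1)].sum() / nk
        start += nk
    ss_among = ss_total - ss_within
    df_among = n_pops - 1
    df_within = n_total - n_pops
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n_prime = (n_total - sum(nk**2 for nk in sizes) / n_total) / df_among
    sigma_a = (ms_among - ms_within) / n_prime
    sigma_w = ms_within
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return sigma_a / denom


def _fst_from_masks(d2: np.ndarray, mask1: np.ndarray) -> float:
    """Fast Phi-ST for two groups given membership mask of group 1."""
    n_total = d2.shape[0]
    n1 = int(mask1.sum())
    n2 = n_total - n1
    total = d2.sum() / 2.0
    w1 = float(mask1 @ d2 @ mask1) / 2.0
    mask2 = 1.0 - mask1
    w2 = float(mask2 @ d2 @ mask2) / 2.0
    ss_total = total / n_total
    ss_within = w1 / n1 + w2 / n2
    ss_among = ss_total - ss_within
    ms_among = ss_among / 1.0
    df_within = n_total - 2
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n_prime = (n_total - (n1**2 + n2**2) / n_total)
    sigma_a = (ms_among - ms_within) / n_prime
    denom = sigma_a + ms_within
    if denom == 0.0:
        return 0.0
    return sigma_a / denom


def _squared_distances(
    ds: PopulationDataset, sample_idx: Sequence[int], mode: str
) -> np.ndarray:
    loci = ds.panel.single_copy
    samples = [ds.samples[i] for i in sample_idx]
    if mode == "haplotype_identity":
        idents = [s.haplotype.identity(loci) for s in samples]
        codes: dict[tuple, int] = {}
        arr = np.array([codes.setdefault(h, len(codes)) for h in idents])
        return (arr[:, None] != arr[None, :]).astype(float)
    if mode == "stepwise":
        rows = []
        for s in samples:
            rows.append([s.haplotype.single_value(l) for l in loci])
        mat = np.asarray(rows, dtype=float)
        diff = mat[:, None, :] - mat[None, :, :]
        return np.nansum(diff**2, axis=2)
    raise ValueError(f"unknown FST mode {mode!r}")


def pairwise_fst(
    ds: PopulationDataset,
    mode: str = "haplotype_identity",
    n_permutations: int = 10_000,
    seed: int = 0,
    by: str = "population",
) -> DistanceMatrix:
    """Pairwise AMOVA FST over single-copy loci with permutation p-values.

    Samples with missing data at any single-copy locus are excluded.
    Populations with fewer than 2 usable samples are skipped (NaN row) with
    a warning.
    """
    loci = ds.panel.single_copy
    groups = list(_group_labels(ds, by))
    if len(groups) < 2:
        raise ValueError("need at least two populations")
    idx_by_group: dict[str, list[int]] = {g: [] for g in groups}
    for i, s in enumerate(ds.samples):
        if s.haplotype.is_complete(loci):
            idx_by_group[getattr(s, by)].append(i)

    p = len(groups)
    values = np.zeros((p, p))
    pvalues = np.ones((p, p))
    rng = np.random.default_rng(seed)
    for a in range(p):
        for b in range(a + 1, p):
            ga, gb = groups[a], groups[b]
            if len(idx_by_group[ga]) < 2 or len(idx_by_group[gb]) < 2:
                warnings.warn(f"skipping pair ({ga}, {gb}): fewer than 2 samples")
                values[a, b] = values[b, a] = np.nan
                pvalues[a, b] = pvalues[b, a] = np.nan
                continue
            idx = idx_by_group[ga] + idx_by_group[gb]
            d2 = _squared_distances(ds, idx, mode)
            n1 = len(idx_by_group[ga])
            mask1 = np.zeros(len(idx))
            mask1[:n1] = 1.0
            obs = _fst_from_masks(d2, mask1)
            exceed = 0
            for _ in range(n_permutations):
                perm = rng.permutation(len(idx))
                pm = np.zeros(len(idx))
                pm[perm[:n1]] = 1.0
                if _fst_from_masks(d2, pm) >= obs - 1e-12:
                    exceed += 1
            values[a, b] = values[b, a] = obs
            pvalues[a, b] = pvalues[b, a] = (exceed + 1) / (n_permutations + 1)
    return DistanceMatrix(
        labels=groups, values=values, pvalues=pvalues,
        n_permutations=n_permutations, mode=mode,
    )


# ---------------------------------------------------------------------------
# PCA on haplogroup frequency matrices


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # populations x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame


def pca_haplogroup_freq(fm: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of a (populations x haplogroups) frequency matrix.

    Covariance PCA on column-centered frequencies via SVD; the sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    if fm.shape[0] < 2:
        raise ValueError("need at least two populations")
    n_components = min(n_components, fm.shape[0] - 1, fm.shape[1])
    x = fm.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-30:
        warnings.warn("constant frequency matrix: zero variance")
        ratios = np.zeros(n_components)
        coords = np.zeros((fm.shape[0], n_components))
        load = np.zeros((fm.shape[1], n_components))
    else:
        for k in range(n_components):
            j = np.argmax(np.abs(vt[k]))
            if vt[k, j] < 0:
                vt[k] *= -1
                u[:, k] *= -1
        ratios = var[:n_components] / total
        coords = u[:, :n_components] * s[:n_components]
        load = vt[:n_components].T
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=fm.index, columns=cols),
        explained_variance_ratio=ratios,
        loadings=pd.DataFrame(load, index=fm.columns, columns=cols),
    )


# ---------------------------------------------------------------------------
# Inverse-distance-weighted frequency surfaces


@dataclass
class FrequencySurface:
    lat: np.ndarray  # grid latitudes (rows)
    lon: np.ndarray  # grid longitudes (columns)
    values: np.ndarray  # rows x cols interpolated frequencies
    stations: list[tuple[float, float, float]]
    power: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, la in enumerate(self.lat):
            for j, lo in enumerate(self.lon):
                rows.append({"latitude": la, "longitude": lo, "value": self.values[i, j]})
        return pd.DataFrame(rows)


def idw_surface(
    stations: Sequence[tuple[float, float, float]],
    cell_size: float = 0.5,
    padding: float = 2.0,
    power: float = 2.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> FrequencySurface:
    """Inverse-distance-weighted surface from (lat, lon, frequency) stations.

    Cell value = sum(w_i f_i)/sum(w_i) with w_i = d_i^-power; a cell within
    half a cell size of a station takes the station value exactly.
    """
    if not stations:
        raise ValueError("need at least one station")
    if power <= 0:
        raise ValueError("power must be positive")
    pts = np.asarray([(la, lo) for la, lo, _ in stations], dtype=float)
    freqs = np.asarray([f for _, _, f in stations], dtype=float)
    uniq: dict[tuple[float, float], float] = {}
    for (la, lo), f in zip(map(tuple, pts), freqs):
        if (la, lo) in uniq and uniq[(la, lo)] != f:
            raise ValueError(f"duplicate station at ({la}, {lo}) with conflicting values")
        uniq[(la, lo)] = f
    if bounds is None:
        bounds = (
            pts[:, 0].min() - padding, pts[:, 0].max() + padding,
            pts[:, 1].min() - padding, pts[:, 1].max() + padding,
        )
    lat = np.arange(bounds[0], bounds[1] + cell_size / 2, cell_size)
    lon = np.arange(bounds[2], bounds[3] + cell_size / 2, cell_size)
    gla, glo = np.meshgrid(lat, lon, indexing="ij")
    d = np.sqrt(
        (gla[..., None] - pts[:, 0]) ** 2 + (glo[..., None] - pts[:, 1]) ** 2
    )
    near = d.min(axis=-1) <= cell_size / 2
    nearest = d.argmin(axis=-1)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=-1)
    denom[denom == 0] = 1.0
    vals = (w * freqs).sum(axis=-1) / denom
    vals[near] = freqs[nearest[near]]
    return FrequencySurface(lat=lat, lon=lon, values=vals, stations=list(stations), power=power)


def population_stations(
    ds: PopulationDataset, haplogroup_prefix: str, by: str = "population"
) -> list[tuple[float, float, float]]:
    """One (lat, lon, clade frequency) station per population."""
    out = []
    for g in _group_labels(ds, by):
        sub = ds.subset(**{by: g})
        inside = sub.subset(haplogroup_prefix=haplogroup_prefix)
        lat = float(np.mean([s.latitude for s in sub.samples]))
        lon = float(np.mean([s.longitude for s in sub.samples]))
        out.append((lat, lon, len(inside) / len(sub)))
    return out
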
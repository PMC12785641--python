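"""Distribution diagnostics for generated ensembles.

Summaries collect the quantities that characterize a batch — unit-cell
volumes, maximal cell lengths, adjacent length ratios, oblique angles,
interatomic-distance histograms and special-position occupancy counts —
and compare them against target distributions with Kolmogorov-Smirnov
statistics.  Plotting is intentionally kept out of the pass/fail logic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .cells import VolumeSpec
from .errors import DomainError
from .placement import CrystalStructure
from .symmetry import SPECIAL, expand_to_unit_cell, min_cell_height, shift_table

__all__ = [
    "EnsembleSummary",
    "summarize_ensemble",
    "ks_distance",
    "check_volume_match",
    "trough_signature",
    "scaled_trough_ratio",
    "CheckReport",
]


@dataclass
class EnsembleSummary:
    volumes: np.ndarray
    max_lengths: np.ndarray
    ratios_21: np.ndarray
    ratios_32: np.ndarray
    beta_angles: np.ndarray
    distance_bin_edges: np.ndarray
    distance_counts: np.ndarray
    occupancy_counts: tuple[int, int, int]  # structures with 0 / 1 / >1 specials

    @property
    def n_structures(self) -> int:
        return int(sum(self.occupancy_counts))


@dataclass
class CheckReport:
    name: str
    statistic: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.statistic <= self.tolerance

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return f"{status}  {self.name}: KS = {self.statistic:.5f} (tol {self.tolerance:g})"


def _pair_distances(structure: CrystalStructure, r_max: float) -> np.ndarray:
    """All interatomic distances up to ``r_max`` over the expanded cell.

    Periodic copies within a shift block wide enough for ``r_max`` are
    included; pure lattice translations of the same image are excluded.
    """
    frac = np.asarray([a.frac for a in structure.atoms], dtype=float)
    if len(frac) == 0:
        return np.empty(0)
    full, _ = expand_to_unit_cell(frac, structure.group)
    n = len(full)
    if n < 2:
        return np.empty(0)
    h = min_cell_height(structure.vectors)
    shifts = shift_table(max(1, int(np.ceil(r_max / h)))).astype(float)
    iu, ju = np.triu_indices(n, k=1)
    delta = full[ju] - full[iu]
    delta -= np.round(delta)
    cart = (delta[:, None, :] + shifts[None, :, :]) @ structure.vectors
    d = np.sqrt(np.sum(cart * cart, axis=2)).ravel()
    return d[d <= r_max]


def summarize_ensemble(
    structures: Sequence[CrystalStructure],
    r_max: float = 5.0,
    bin_width: float = 0.05,
) -> EnsembleSummary:
    """Deterministic per-batch summaries of the diagnostic quantities."""
    if len(structures) == 0:
        raise DomainError("need at least one structure")
    volumes, max_lengths, r21, r32, betas = [], [], [], [], []
    occupancy = [0, 0, 0]
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for s in structures:
        volumes.append(s.volume)
        lengths = sorted(s.parameters[:3])
        max_lengths.append(lengths[2])
        r21.append(lengths[1] / lengths[0])
        r32.append(lengths[2] / lengths[1])
        betas.append(s.parameters.beta)
        n_special = sum(1 for a in s.atoms if a.site.kind == SPECIAL)
        occupancy[min(n_special, 2)] += 1
        hist, _ = np.histogram(_pair_distances(s, r_max), bins=edges)
        counts += hist
    return EnsembleSummary(
        volumes=np.asarray(volumes),
        max_lengths=np.asarray(max_lengths),
        ratios_21=np.asarray(r21),
        ratios_32=np.asarray(r32),
        beta_angles=np.asarray(betas),
        distance_bin_edges=edges,
        distance_counts=counts,
        occupancy_counts=(occupancy[0], occupancy[1], occupancy[2]),
    )


def ks_distance(sample_a, sample_b_or_cdf) -> float:
    """Kolmogorov-Smirnov statistic, two-sample or against an analytic c.d.f."""
    a = np.asarray(sample_a, dtype=float)
    if a.size == 0:
        raise DomainError("sample must be non-empty")
    if callable(sample_b_or_cdf):
        return float(stats.kstest(a, sample_b_or_cdf).statistic)
    b = np.asarray(sample_b_or_cdf, dtype=float)
    if b.size == 0:
        raise DomainError("sample must be non-empty")
    return float(stats.ks_2samp(a, b).statistic)


def _volume_cdf(spec: VolumeSpec) -> Callable[[np.ndarray], np.ndarray]:
    if spec.family == "lognormal":
        return stats.lognorm(s=spec.sigma, scale=np.exp(spec.mu)).cdf
    return stats.uniform(loc=spec.vmin, scale=spec.vmax - spec.vmin).cdf


def check_volume_match(
    volumes: np.ndarray | EnsembleSummary,
    spec: VolumeSpec,
    tolerance: float = 0.01,
) -> CheckReport:
    """KS test of an ensemble's volume sample against the target spec."""
    if isinstance(volumes, EnsembleSummary):
        volumes = volumes.volumes
    v = np.asarray(volumes, dtype=float)
    if v.size < 1:
        raise DomainError("empty volume sample")
    return CheckReport(
        name=f"volume vs {spec.family}",
        statistic=ks_distance(v, _volume_cdf(spec)),
        tolerance=tolerance,
    )


def trough_signature(
    summary: EnsembleSummary,
    trough_span: tuple[float, float] = (1.7, 2.28),
    peak_span: tuple[float, float] = (1.3, 1.7),
) -> float:
    """Ratio of trough-window to bonded-peak histogram mass.

    Artificial-molecule ensembles show a bonded peak followed by a
    depleted trough before the non-bonded onset; uniform placement does
    not.  Small values (<< 1) indicate the molecule-like signature.
    """
    edges = summary.distance_bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = summary.distance_counts[(centers >= peak_span[0]) & (centers < peak_span[1])].sum()
    trough = summary.distance_counts[
        (centers >= trough_span[0]) & (centers < trough_span[1])
    ].sum()
    if peak == 0:
        return float("inf")
    return float(trough / peak)


def scaled_trough_ratio(
    structures: Sequence[CrystalStructure],
    table=None,
    peak_span: tuple[float, float] = (0.9, 1.1),
    trough_span: tuple[float, float] = (1.1, 1.5),
    r_max_scaled: float = 3.0,
) -> float:
    """Trough-to-peak mass ratio in units of summed covalent radii.

    For every interatomic pair (expanded cell, periodic images included)
    the distance is divided by the sum of the two covalent radii; bonded
    contacts land near 1, the depleted zone between one and two bond
    lengths corresponds to ``trough_span``.  Absolute-length windows
    cannot express this signature once pairs of very different radii mix
    (hydrogen contacts overlap the heavy-atom trough), hence the scaling.
    Molecule-like ensembles give ratios near 0; uniform placement gives
    ratios well above 1.
    """
    from .placement import ElementFrequencyTable

    if table is None:
        table = ElementFrequencyTable.default()
    peak = 0.0
    trough = 0.0
    for s in structures:
        frac = np.asarray([a.frac for a in s.atoms], dtype=float)
        if len(frac) < 2:
            continue
        full, parent = expand_to_unit_cell(frac, s.group)
        radii = np.asarray([table.radius(s.atoms[i].element) for i in parent])
        n = len(full)
        if n < 2:
            continue
        h = min_cell_height(s.vectors)
        r_max = r_max_scaled * 2 * radii.max()
        shifts = shift_table(max(1, int(np.ceil(r_max / h)))).astype(float)
        iu, ju = np.triu_indices(n, k=1)
        delta = full[ju] - full[iu]
        delta -= np.round(delta)
        cart = (delta[:, None, :] + shifts[None, :, :]) @ s.vectors
        d = np.sqrt(np.sum(cart * cart, axis=2))
        scaled = d / (radii[iu] + radii[ju])[:, None]
        peak += float(np.sum((scaled >= peak_span[0]) & (scaled < peak_span[1])))
        trough += float(np.sum((scaled >= trough_span[0]) & (scaled < trough_span[1])))
    if peak == 0:
        return float("inf")
    return trough / peak
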
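"""Coulomb site-potential probe over point-charge snapshots.

Evaluates the bare electrostatic potential V = k_e Σ q_i / r_i (charges in e,
distances in Å, potentials in V, k_e = 14.399645 V·Å/e) generated by the MM
point-charge environment at the unweighted centroid ("mean point") of a
nucleobase site, per snapshot, producing a potential time series.  The probed
site's own atoms are excluded from the sum by default; no periodic images, no
reaction field, optional spherical cutoff for experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KE_V_ANG_PER_E
from .errors import InvalidParameterError, SingularityError
from .trajectory import Trace

__all__ = [
    "ChargeSnapshot",
    "site_midpoint",
    "coulomb_potential",
    "potential_trace",
]

#: Probe-to-atom distance below which the Coulomb sum is singular (Å).
SINGULARITY_DISTANCE = 1e-6


@dataclass
class ChargeSnapshot:
    """Point charges of one trajectory frame with site-membership labels.

    ``ids`` are 1-based atom identifiers matching file order; ``sites`` maps a
    site label to the member atom ids.  The total charge of the snapshot is
    reported, not constrained.
    """

    coords: np.ndarray  # (N, 3) Å
    charges: np.ndarray  # (N,) e
    ids: np.ndarray | None = None
    names: list[str] | None = None
    resnames: list[str] | None = None
    radii: np.ndarray | None = None
    sites: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidParameterError("coords must have shape (N, 3)")
        n = self.coords.shape[0]
        if self.charges.shape != (n,):
            raise InvalidParameterError("charges must have shape (N,)")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidParameterError("coordinates must be finite")
        if self.ids is None:
            self.ids = np.arange(1, n + 1, dtype=int)
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if self.ids.shape != (n,):
                raise InvalidParameterError("ids must have shape (N,)")
        self._id_to_index = {int(a): i for i, a in enumerate(self.ids)}

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def site_indices(self, site: str) -> np.ndarray:
        if site not in self.sites:
            raise InvalidParameterError(
                f"unknown site {site!r}; known: {sorted(self.sites)}"
            )
        try:
            return np.array([self._id_to_index[int(a)] for a in self.sites[site]])
        except KeyError as exc:
            raise InvalidParameterError(
                f"site {site!r} references atom id {exc.args[0]} absent from snapshot"
            ) from None


def site_midpoint(snapshot: ChargeSnapshot, site: str) -> np.ndarray:
    """Unweighted arithmetic mean of the site's member-atom coordinates (Å)."""
    idx = snapshot.site_indices(site)
    if idx.size == 0:
        raise InvalidParameterError(f"site {site!r} has no atoms")
    return snapshot.coords[idx].mean(axis=0)


def coulomb_potential(
    snapshot: ChargeSnapshot,
    point: Sequence[float],
    exclude_site: str | None = None,
    cutoff: float | None = None,
) -> float:
    """Bare Coulomb potential (V) at ``point`` from all non-excluded charges.

    ``exclude_site`` removes that site's atoms from the sum (the probed site's
    own atoms are unphysical sources for its probe).  ``cutoff`` (Å) drops
    sources beyond a sphere; default is no cutoff and no periodicity.

    Raises
    ------
    SingularityError
        If an included atom lies within 1e-6 Å of the probe point.
    """
    point = np.asarray(point, dtype=float)
    mask = np.ones(snapshot.n_atoms, dtype=bool)
    if exclude_site is not None:
        mask[snapshot.site_indices(exclude_site)] = False
    r = np.linalg.norm(snapshot.coords[mask] - point, axis=1)
    too_close = r < SINGULARITY_DISTANCE
    if np.any(too_close):
        offender = snapshot.ids[mask][too_close][0]
        raise SingularityError(
            f"atom id {int(offender)} coincides with the probe point "
            f"(r < {SINGULARITY_DISTANCE} Å)"
        )
    q = snapshot.charges[mask]
    if cutoff is not None:
        within = r <= cutoff
        r, q = r[within], q[within]
    return float(KE_V_ANG_PER_E * np.sum(q / r))


def potential_trace(
    snapshots: Sequence[ChargeSnapshot],
    site: str,
    times: np.ndarray | None = None,
    dt: float = 1.0,
    cutoff: float | None = None,
) -> Trace:
    """Per-snapshot Coulomb potential at the per-snapshot site midpoint.

    The probe point is recomputed each frame from the site's (possibly moving)
    atoms and the site's own atoms are excluded from the sum.  ``times`` (ps)
    defaults to a uniform grid of step ``dt``.  The result feeds the
    trajectory statistics (replicate averaging, Fourier spectrum).
    """
    if not snapshots:
        raise InvalidParameterError("need at least one snapshot")
    values = np.empty(len(snapshots))
    for k, snap in enumerate(snapshots):
        probe = site_midpoint(snap, site)
        values[k] = coulomb_potential(snap, probe, exclude_site=site, cutoff=cutoff)
    if times is None:
        times = np.arange(len(snapshots)) * dt
    return Trace(times=np.asarray(times, dtype=float), values=values, label=site)
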
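"""Readers and writers for the package's plain-text formats.

Traces travel as TSV (``time_ps`` + either ``value`` or
``e_donor_eV``/``e_acceptor_eV``, optional ``replicate``), point-charge
trajectories as multi-model PQR, site memberships and rate parameters as JSON.
All parsers raise typed errors with 1-based line numbers where possible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .electrostatics import ChargeSnapshot
from .errors import ConfigError, HoleHopError, ParseError, StructuralError
from .kinetics import RateSet, activation_rate_from_time
from .trajectory import SiteEnergyTrace, Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_pqr",
    "write_pqr",
    "read_site_map",
    "write_site_map",
    "read_rates",
]

_SINGLE_COLS = {"time_ps", "value"}
_PAIR_COLS = {"time_ps", "e_donor_eV", "e_acceptor_eV"}


def _numeric(df: pd.DataFrame, col: str) -> np.ndarray:
    series = pd.to_numeric(df[col], errors="coerce")
    bad = series.index[series.isna() & df[col].notna()]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based indexing.
        raise ParseError(f"non-numeric value in column {col!r}", line=int(bad[0]) + 2)
    if series.isna().any():
        row = int(series.index[series.isna()][0])
        raise ParseError(f"missing value in column {col!r}", line=row + 2)
    return series.to_numpy(dtype=float)


def read_trace(path):
    """Read a trace TSV.

    Returns a :class:`Trace` (``time_ps``/``value`` layout) or a
    :class:`SiteEnergyTrace` (donor/acceptor layout).  A ``replicate`` column
    with several distinct values yields a list of traces, one per replicate,
    in ascending replicate order.  The time grid must be uniform and strictly
    increasing; violations raise :class:`~holehop.errors.ParseError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    cols = set(df.columns)
    if _PAIR_COLS <= cols:
        kind = "pair"
    elif _SINGLE_COLS <= cols:
        kind = "single"
    else:
        raise ParseError(
            f"{path}: expected columns {sorted(_SINGLE_COLS)} or "
            f"{sorted(_PAIR_COLS)}, found {sorted(cols)}"
        )
    if df.empty:
        raise ParseError(f"{path}: no data rows")

    def build(sub: pd.DataFrame, replicate: int | None):
        times = _numeric(sub, "time_ps")
        order = np.argsort(times, kind="stable")
        if not np.array_equal(order, np.arange(len(times))):
            raise ParseError(
                "time_ps is not strictly increasing",
                line=int(sub.index[int(order[0])]) + 2,
            )
        try:
            if kind == "single":
                return Trace(times=times, values=_numeric(sub, "value"),
                             replicate=replicate)
            return SiteEnergyTrace(
                times=times,
                e_donor=_numeric(sub, "e_donor_eV"),
                e_acceptor=_numeric(sub, "e_acceptor_eV"),
                replicate=replicate,
            )
        except HoleHopError as exc:
            raise ParseError(f"{path}: {exc}") from exc

    if "replicate" in cols:
        reps = _numeric(df, "replicate").astype(int)
        unique = sorted(set(reps.tolist()))
        if len(unique) > 1:
            return [build(df[reps == r], r) for r in unique]
        return build(df, unique[0])
    return build(df, None)


def write_trace(path, trace) -> None:
    """Write a trace (or list of replicate traces) as TSV, 10 significant digits."""
    path = Path(path)
    traces = trace if isinstance(trace, (list, tuple)) else [trace]
    frames = []
    for t in traces:
        if isinstance(t, SiteEnergyTrace):
            frame = pd.DataFrame(
                {"time_ps": t.times, "e_donor_eV": t.e_donor,
                 "e_acceptor_eV": t.e_acceptor}
            )
        else:
            frame = pd.DataFrame({"time_ps": t.times, "value": t.values})
        if t.replicate is not None:
            frame["replicate"] = t.replicate
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# --- PQR ---------------------------------------------------------------

_PQR_FORMAT = (
    "ATOM  {serial:>5d} {name:<4s} {resname:<4s} {resseq:>4d}    "
    "{x:10.4f} {y:10.4f} {z:10.4f} {q:8.4f} {r:7.4f}\n"
)


def write_pqr(path, snapshots: Sequence[ChargeSnapshot]) -> None:
    """Write snapshots as multi-model PQR (radius column written as zeros)."""
    path = Path(path)
    with open(path, "w") as fh:
        for model, snap in enumerate(snapshots, start=1):
            if len(snapshots) > 1:
                fh.write(f"MODEL {model:>8d}\n")
            names = snap.names or ["X"] * snap.n_atoms
            resnames = snap.resnames or ["MOL"] * snap.n_atoms
            radii = snap.radii if snap.radii is not None else np.zeros(snap.n_atoms)
            for i in range(snap.n_atoms):
                fh.write(_PQR_FORMAT.format(
                    serial=int(snap.ids[i]), name=names[i][:4],
                    resname=resnames[i][:4], resseq=1,
                    x=snap.coords[i, 0], y=snap.coords[i, 1], z=snap.coords[i, 2],
                    q=snap.charges[i], r=float(radii[i]),
                ))
            if len(snapshots) > 1:
                fh.write("ENDMDL\n")
        if len(snapshots) == 1:
            fh.write("END\n")


def read_pqr(path, sites: dict[str, list[int]] | None = None) -> list[ChargeSnapshot]:
    """Read a (multi-model) PQR file into per-frame charge snapshots.

    PQR is whitespace-delimited; the last five fields of each ATOM/HETATM
    record are taken as x, y, z, charge, radius so an optional chain column
    does not break parsing.  Atom order is preserved and ids are 1-based file
    order.  Inconsistent atom counts across models raise
    :class:`~holehop.errors.StructuralError`.
    """
    path = Path(path)
    frames: list[list[tuple]] = []
    current: list[tuple] | None = None
    seen_model = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw.split(None, 1)[0].upper() if raw.strip() else ""
            if rec == "MODEL":
                seen_model = True
                if current:
                    frames.append(current)
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                current = None
            elif rec in ("ATOM", "HETATM"):
                tokens = raw.split()
                if len(tokens) < 8:
                    raise ParseError("too few fields in atom record", line=lineno)
                try:
                    x, y, z, q, _radius = (float(v) for v in tokens[-5:])
                except ValueError:
                    raise ParseError(
                        "non-numeric coordinate/charge field", line=lineno
                    ) from None
                name = tokens[2] if len(tokens) > 2 else "X"
                resname = tokens[3] if len(tokens) > 3 else "MOL"
                if current is None:
                    current = []
                current.append((name, resname, x, y, z, q, _radius))
    if current:
        frames.append(current)
    if not frames:
        raise ParseError(f"{path}: no atom records found")
    n0 = len(frames[0])
    for k, frame in enumerate(frames):
        if len(frame) != n0:
            raise StructuralError(
                f"model {k + 1} has {len(frame)} atoms, expected {n0}"
            )
    if not seen_model and len(frames) != 1:  # pragma: no cover - defensive
        raise StructuralError("inconsistent MODEL/ENDMDL structure")
    snapshots = []
    for frame in frames:
        names = [a[0] for a in frame]
        resnames = [a[1] for a in frame]
        coords = np.array([a[2:5] for a in frame], dtype=float)
        charges = np.array([a[5] for a in frame], dtype=float)
        radii = np.array([a[6] for a in frame], dtype=float)
        snapshots.append(ChargeSnapshot(
            coords=coords, charges=charges, names=names, resnames=resnames,
            radii=radii, sites=dict(sites) if sites else {},
        ))
    return snapshots


def read_site_map(path) -> dict[str, list[int]]:
    """Site-membership JSON: {site label: [1-based atom ids in file order]}."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: site map must be a JSON object")
    out: dict[str, list[int]] = {}
    for label, ids in data.items():
        if not isinstance(ids, list) or not all(
            isinstance(i, int) and i >= 1 for i in ids
        ):
            raise ParseError(f"{path}: site {label!r} must list 1-based integer ids")
        out[str(label)] = list(ids)
    return out


def write_site_map(path, sites: dict[str, list[int]]) -> None:
    with open(path, "w") as fh:
        json.dump({k: [int(i) for i in v] for k, v in sites.items()}, fh, indent=1)
        fh.write("\n")


_RATE_KEYS = {
    "k_act0", "tau_act_ps", "dE_DA_eV", "dE_AD_eV", "k_rel_D", "k_rel_A",
    "k_HT", "k_dam_D", "k_dam_A", "temperature_K",
}


def read_rates(source) -> RateSet:
    """Build a :class:`~holehop.kinetics.RateSet` from JSON (path or dict).

    ``k_act0`` may be a rate in s⁻¹ or the object ``{"tau_act_ps": ...}``
    (the activation time picture, k = 1/τ with no separate barrier, so
    ``dE_DA_eV`` then defaults to 0).  Missing relaxation/damage rates fall
    back to the experimentally anchored defaults (1e13, 1e7, 3e6 s⁻¹); unknown
    keys are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = json.load(fh)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("rates JSON must be an object")
    unknown = set(data) - _RATE_KEYS
    if unknown:
        raise ConfigError(f"unknown rate keys: {sorted(unknown)}")
    k_act0 = data.get("k_act0")
    if isinstance(k_act0, dict):
        extra = set(k_act0) - {"tau_act_ps"}
        if extra:
            raise ConfigError(f"unknown keys under k_act0: {sorted(extra)}")
        k_act0 = activation_rate_from_time(float(k_act0["tau_act_ps"]))
    elif "tau_act_ps" in data:
        if k_act0 is not None:
            raise ConfigError("give either k_act0 or tau_act_ps, not both")
        k_act0 = activation_rate_from_time(float(data["tau_act_ps"]))
    if k_act0 is None:
        raise ConfigError("rates JSON must define k_act0 or tau_act_ps")
    return RateSet(
        k_act0=float(k_act0),
        dE_DA=float(data.get("dE_DA_eV", 0.0)),
        dE_AD=float(data.get("dE_AD_eV", 0.3)),
        k_rel_D=float(data.get("k_rel_D", 1e13)),
        k_rel_A=float(data.get("k_rel_A", 1e13)),
        k_HT=float(data.get("k_HT", 0.0)),
        k_dam_D=float(data.get("k_dam_D", 1e7)),
        k_dam_A=float(data.get("k_dam_A", 3e6)),
        temperature=float(data.get("temperature_K", 300.0)),
    )
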
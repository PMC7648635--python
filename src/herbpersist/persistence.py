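"""Weighted residence time (WRT): a fine-scale species persistence index.

For one species in one permanent quadrat surveyed Z times, let P be the
number of surveys at which it was present and T the number of maximal runs
of consecutive presences.  Then

    WRT_pa = 100 * (P / T) / Z        (percent; 0 when never present)

so a species present throughout scores 100, and a species flickering in and
out every other survey scores 100/Z.  The abundance-weighted variant
multiplies WRT_pa by the species' mean relative cover in that quadrat:

    WRT_abu = WRT_pa * Rel.cov,   Rel.cov in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import SurveySeries

__all__ = ["PersistenceRecord", "presence_runs", "wrt_pa", "rel_cover",
           "wrt_abu", "wrt_table", "wrt_frame"]


@dataclass(frozen=True)
class PersistenceRecord:
    """Per (species, unit) persistence summary: P, T, Z and the WRT values."""

    species: str
    unit: str
    P: int
    T: int
    Z: int
    wrt_pa: float
    relcov: float
    wrt_abu: float


def presence_runs(pattern) -> int:
    """Number of maximal runs of consecutive presences in a boolean sequence.

    Equals the number of absence-to-presence transitions, counting the start
    as an absence.  0 for an all-absent pattern.
    """
    p = np.asarray(pattern, dtype=bool)
    if p.size == 0:
        raise ValueError("empty presence pattern")
    return int(p[0]) + int(np.count_nonzero(p[1:] & ~p[:-1]))


def wrt_pa(pattern) -> float:
    """Presence/absence weighted residence time, in percent of the series."""
    p = np.asarray(pattern, dtype=bool)
    if p.size == 0:
        raise ValueError("empty presence pattern")
    t = presence_runs(p)
    if t == 0:
        return 0.0
    return 100.0 * (int(p.sum()) / t) / p.size


def rel_cover(covers, totals, mode: str = "presence_only") -> float:
    """Mean relative cover of a focal species in one unit over the series.

    Parameters
    ----------
    covers, totals:
        Per-survey cover of the focal species and summed cover of all species
        in the unit (same length Z, totals >= covers elementwise).
    mode:
        ``"presence_only"`` (default) averages the per-survey share
        cover/total over the surveys where the species was present;
        ``"all_surveys"`` averages over all Z surveys, absences contributing 0.

    Returns a proportion in [0, 1]; 0 for a species never present.
    """
    c = np.asarray(covers, dtype=float)
    t = np.asarray(totals, dtype=float)
    if c.shape != t.shape:
        raise ValueError("covers and totals must have equal length")
    if np.any(c < 0) or np.any(t < c):
        raise ValueError("need totals >= covers >= 0 elementwise")
    if np.any((t == 0) & (c > 0)):
        raise ValueError("zero unit total at a survey with positive cover")
    present = c > 0
    if not present.any():
        return 0.0
    share = np.zeros_like(c)
    share[present] = c[present] / t[present]
    if mode == "presence_only":
        return float(share[present].mean())
    if mode == "all_surveys":
        return float(share.mean())
    raise ValueError(f"unknown rel_cover mode {mode!r}")


def wrt_abu(wrt_pa_value: float, relcov: float) -> float:
    """Abundance-weighted residence time: WRT_pa times mean relative cover."""
    if not 0 <= wrt_pa_value <= 100:
        raise ValueError("wrt_pa_value must lie in [0, 100]")
    if not 0 <= relcov <= 1:
        raise ValueError("relcov must lie in [0, 1]")
    return wrt_pa_value * relcov


def wrt_table(series: SurveySeries, mode: str = "presence_only") -> list[PersistenceRecord]:
    """WRT records for every (species, unit) with at least one presence.

    Relative cover uses occupancy-aware shares: the per-survey total is the
    summed cover of all species in the unit at that survey.
    """
    occ = series.occupancy
    cov = series.cover
    z = series.n_surveys
    totals = cov.sum(axis=1)  # unit x survey
    records: list[PersistenceRecord] = []
    for iu, unit in enumerate(series.units):
        for isp, sp in enumerate(series.species):
            patt = occ[iu, isp]
            if not patt.any():
                continue
            p = int(patt.sum())
            t = presence_runs(patt)
            w = 100.0 * (p / t) / z
            rc = rel_cover(cov[iu, isp], totals[iu], mode=mode)
            records.append(PersistenceRecord(sp, unit, p, t, z, w, rc, w * rc))
    return records


def wrt_frame(series: SurveySeries, mode: str = "presence_only",
              round_to: int | None = None) -> pd.DataFrame:
    """WRT table as a DataFrame; ``round_to`` rounds the reported values
    (one decimal is the reporting convention) while computation stays exact."""
    recs = wrt_table(series, mode=mode)
    df = pd.DataFrame([{
        "site": series.site_id, "unit": r.unit, "species": r.species,
        "P": r.P, "T": r.T, "Z": r.Z, "wrt_pa": r.wrt_pa,
        "relcov": r.relcov, "wrt_abu": r.wrt_abu,
    } for r in recs])
    if round_to is not None and not df.empty:
        for col in ("wrt_pa", "relcov", "wrt_abu"):
            df[col] = df[col].round(round_to)
    return df
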
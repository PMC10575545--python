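"""Pseudo-autosomal boundary detection.

Two evidence lines: (i) the female:male DNA read-depth ratio along the Z,
normalised per sex by the autosomal median and expected to drop from
log2(1) = 0 inside the diploid PAR to log2(0.5) = -1 outside; and (ii) the
extent of female heterozygosity, which stops at the end of the recombining
PAR. The coverage boundary is a least-squares two-segment change-point with
a minimum mean-separation constraint; the heterozygosity boundary is the
position after the last female-heterozygous site; the consensus prefers
heterozygosity when it agrees with the coverage change-point to within one
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from zdose.datamodel import ValidationError


def normalized_fm_coverage(tracks: dict[str, pd.DataFrame],
                           autosome_names: list[str],
                           z_name: str) -> pd.DataFrame:
    """Per-window log2(f:m) coverage on the Z after per-sex autosomal
    normalisation.

    Each sex's window depth is divided by that sex's median depth over the
    listed autosomes; windows with zero male depth are masked (NaN), not
    +-inf.
    """
    norm = {}
    for sex in ("F", "M"):
        cov = tracks[sex]
        auto = cov[cov["chrom"].isin(autosome_names)]
        if auto.empty:
            raise ValidationError(f"no autosomal windows for sex {sex}")
        med = float(auto["depth"].median())
        if med == 0:
            raise ValidationError(f"zero autosomal median depth for sex {sex}")
        z = cov[cov["chrom"] == z_name].sort_values("start").reset_index(drop=True)
        norm[sex] = z.assign(norm=z["depth"] / med)
    f, m = norm["F"], norm["M"]
    if len(f) != len(m) or not (f["start"].to_numpy() == m["start"].to_numpy()).all():
        raise ValidationError("female and male Z windows are not aligned")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            m["norm"].to_numpy() > 0,
            np.log2(f["norm"].to_numpy() / m["norm"].to_numpy()),
            np.nan,
        )
    return pd.DataFrame({
        "chrom": z_name, "start": f["start"], "end": f["end"], "log2_fm": ratio,
    })


@dataclass
class ParCall:
    detected: bool
    boundary: int | None            # consensus boundary, bp
    coverage_boundary: int | None
    het_boundary: int | None
    discrepancy: bool               # evidence lines disagree by > 1 window
    evidence: str                   # coverage | heterozygosity | consensus | none


def _two_segment_changepoint(values: np.ndarray, min_separation: float
                             ) -> int | None:
    """Index b (1..n-1) splitting values into [0:b), [b:n) minimising the
    two-segment squared error, subject to mean(left) - mean(right) >=
    min_separation. Exhaustive over all split points. None if no split
    satisfies the constraint."""
    n = len(values)
    best_b, best_sse = None, np.inf
    cum = np.concatenate([[0.0], np.cumsum(values)])
    cum2 = np.concatenate([[0.0], np.cumsum(values ** 2)])
    for b in range(1, n):
        nl, nr = b, n - b
        sl, sr = cum[b], cum[n] - cum[b]
        ml, mr = sl / nl, sr / nr
        if ml - mr < min_separation:
            continue
        sse = (cum2[b] - sl * sl / nl) + (cum2[n] - cum2[b] - sr * sr / nr)
        if sse < best_sse:
            best_b, best_sse = b, sse
    return best_b


def detect_par_boundary(fm_track: pd.DataFrame,
                        het_positions: np.ndarray | None = None,
                        min_separation: float = 0.5) -> ParCall:
    """Locate the PAR boundary on the Z.

    ``fm_track`` is the output of :func:`normalized_fm_coverage` ordered by
    position (masked windows are dropped before fitting). The coverage
    boundary is the end coordinate of the last left-segment window of the
    best two-segment fit whose left mean exceeds the right mean by at least
    ``min_separation`` (log2 units; 0.5 reflects the expected 1 -> 0.5
    ploidy drop). If no split qualifies, no PAR is reported (not an error).
    """
    track = fm_track.dropna(subset=["log2_fm"]).sort_values("start")
    if len(track) < 4:
        raise ValidationError("need >= 4 evaluable windows")
    values = track["log2_fm"].to_numpy(dtype=float)
    b = _two_segment_changepoint(values, min_separation)
    het_boundary = None
    if het_positions is not None and len(het_positions) > 0:
        het_boundary = int(np.max(het_positions)) + 1
    if b is None:
        return ParCall(
            detected=False, boundary=None, coverage_boundary=None,
            het_boundary=het_boundary, discrepancy=False, evidence="none",
        )
    cov_boundary = int(track["end"].to_numpy()[b - 1])
    window = int(np.median(track["end"].to_numpy() - track["start"].to_numpy()))
    if het_boundary is None:
        return ParCall(True, cov_boundary, cov_boundary, None, False, "coverage")
    if abs(het_boundary - cov_boundary) <= window:
        return ParCall(True, het_boundary, cov_boundary, het_boundary,
                       False, "consensus")
    return ParCall(True, cov_boundary, cov_boundary, het_boundary,
                   True, "coverage")


def region_fm_coverage(tracks: dict[str, pd.DataFrame],
                       autosome_names: list[str], z_name: str,
                       regions: pd.DataFrame) -> pd.DataFrame:
    """Mean normalised f:m coverage in supplied BED-style regions on the Z
    (gametolog-region style summaries)."""
    fm = normalized_fm_coverage(tracks, autosome_names, z_name)
    mids = ((fm["start"] + fm["end"]) // 2).to_numpy()
    vals = fm["log2_fm"].to_numpy()
    rows = []
    for r in regions.itertuples(index=False):
        sel = (mids >= r.start) & (mids < r.end)
        mean = float(np.nanmean(vals[sel])) if sel.any() else np.nan
        rows.append((r.start, r.end, mean, int(sel.sum())))
    return pd.DataFrame(rows, columns=["start", "end", "mean_log2_fm", "n_windows"])
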
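"""Dose-volume statistics: DVH curves, Dx/Vx metrics, T:N, volume change.

Conventions (config-exposed where the literature is ambiguous):

* Dx — minimum dose received by the most-irradiated x% of the region
  volume, from exactly sorted voxel doses (linear interpolation between
  voxel ranks, never from the binned curve);
* Vx — percent of the region volume receiving *more than* x Gy (strict
  inequality, matching the verbal "receiving more than 60 Gy" definition;
  ``inclusive=True`` switches to ≥);
* T:N — ratio of the mean absorbed dose in the tumor mass to that in the
  normal cortex, where cortex excludes the mass by label-map construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosemap import DoseMap
from .grid import Volume
from .phantom import LABELS


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram for one region."""

    bin_edges_gy: np.ndarray       # (B+1,) dose bin edges starting at 0
    volume_fraction_pct: np.ndarray  # (B+1,) % of region volume with dose >= edge
    region: str = ""
    total_volume_ml: float = 0.0

    def d_at_volume(self, pct: float) -> float:
        """Dose at which the curve crosses the given volume percentage."""
        # curve is non-increasing; interpolate on the flipped axis
        return float(np.interp(pct, self.volume_fraction_pct[::-1],
                               self.bin_edges_gy[::-1]))


def cumulative_dvh(dose: DoseMap, mask: np.ndarray, bin_width_gy: float = 1.0,
                   region: str = "") -> DVHCurve:
    """Exact cumulative DVH over the masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    d = dose.data[mask]
    top = max(float(d.max()), bin_width_gy)
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    frac = (d[None, :] >= edges[:, None]).mean(axis=1) * 100.0
    frac[0] = 100.0  # all voxels receive >= 0 Gy by definition
    vol_ml = mask.sum() * dose.grid.voxel_volume_mm3 * 1e-3
    return DVHCurve(edges, frac, region=region, total_volume_ml=vol_ml)


def dx(dose_values: np.ndarray, x_pct: float) -> float:
    """Minimum dose to the most-irradiated x% of the volume (sorted voxels)."""
    if not 0.0 < x_pct <= 100.0:
        raise ValueError("x must be in (0, 100]")
    d = np.sort(np.asarray(dose_values, dtype=float))[::-1]
    # linear interpolation between voxel ranks; rank x%·N marks the cut
    target = x_pct / 100.0 * len(d)
    lo = int(np.ceil(target)) - 1
    lo = min(max(lo, 0), len(d) - 1)
    if abs(target - round(target)) < 1e-9 or lo == len(d) - 1:
        return float(d[lo])
    w = target - np.floor(target)
    return float(d[lo] * (1 - w) + d[min(lo + 1, len(d) - 1)] * w)


def vx(dose_values: np.ndarray, threshold_gy: float, inclusive: bool = False) -> float:
    """Percent of the volume receiving more than (or at least) the threshold."""
    if threshold_gy < 0:
        raise ValueError("threshold must be >= 0")
    d = np.asarray(dose_values, dtype=float)
    hit = d >= threshold_gy if inclusive else d > threshold_gy
    return float(hit.mean() * 100.0)


@dataclass
class RegionMetrics:
    """Per-region dose summary (one column of the study's dose tables)."""

    region: str
    mean_gy: float
    max_gy: float
    d_gy: dict = field(default_factory=dict)     # {x: Dx}
    v_pct: dict = field(default_factory=dict)    # {threshold: Vx}
    volume_ml: float = 0.0
    delivery: str = "extended"


def dose_metrics(dose: DoseMap, mask: np.ndarray,
                 x_list: tuple[float, ...] = (10, 30, 50, 70, 90),
                 v_thresholds: tuple[float, ...] = (20, 30, 50, 60, 80, 100),
                 region: str = "", inclusive_vx: bool = False) -> RegionMetrics:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    d = dose.data[mask]
    return RegionMetrics(
        region=region,
        mean_gy=float(d.mean()),
        max_gy=float(d.max()),
        d_gy={x: dx(d, x) for x in x_list},
        v_pct={t: vx(d, t, inclusive_vx) for t in v_thresholds},
        volume_ml=float(mask.sum() * dose.grid.voxel_volume_mm3 * 1e-3),
        delivery=dose.delivery,
    )


def t_n_ratio(tumor_mean_gy: float, cortex_mean_gy: float) -> float:
    """Tumor-to-normal ratio of mean absorbed dose (mass vs uninvolved cortex)."""
    if cortex_mean_gy <= 0:
        raise ValueError("cortex mean dose must be positive")
    return tumor_mean_gy / cortex_mean_gy


def volume_change_pct(pre_volume_ml: float, post_volume_ml: float) -> float:
    """Relative mass-volume change, percent; negative means shrinkage."""
    if pre_volume_ml <= 0:
        raise ValueError("pre-treatment volume must be positive")
    return 100.0 * (post_volume_ml - pre_volume_ml) / pre_volume_ml


@dataclass
class RegionDoseReport:
    """Full per-region metric table for one dose map (and optionally its
    truncated-delivery twin), in the shape of the study's dose tables."""

    metrics: dict                      # {region: RegionMetrics}
    t_n: float | None = None
    delivery: str = "extended"
    actual: "RegionDoseReport | None" = None

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for region, m in self.metrics.items():
            row = {"mean_gy": m.mean_gy, "max_gy": m.max_gy, "volume_ml": m.volume_ml}
            row.update({f"d{int(x)}_gy": v for x, v in m.d_gy.items()})
            row.update({f"v{int(t)}_pct": v for t, v in m.v_pct.items()})
            rows[region] = row
        df = pd.DataFrame(rows).T
        df.index.name = "region"
        if self.t_n is not None:
            df["t_n"] = np.nan
            if "tumor" in df.index:
                df.loc["tumor", "t_n"] = self.t_n
        return df


DEFAULT_REGIONS = {
    "tumor": (LABELS["tumor"],),
    "deep_gray": (LABELS["deep_gray"],),
    "cortex": (LABELS["cortex"],),
    "hemisphere": (LABELS["cortex"], LABELS["deep_gray"], LABELS["tumor"],
                   LABELS["necrotic_core"]),
}


def region_report(dose: DoseMap, labels: Volume,
                  regions: dict[str, tuple[int, ...]] | None = None,
                  x_list: tuple[float, ...] = (10, 30, 50, 70, 90),
                  v_thresholds: tuple[float, ...] = (20, 30, 50, 60, 80, 100),
                  truncation_h: float | None = None,
                  inclusive_vx: bool = False) -> RegionDoseReport:
    """Per-region metric table, with T:N when both tumor and cortex exist.

    ``truncation_h`` additionally produces the "actual" (dose delivered up
    to that time) companion table, mirroring extended-vs-actual reporting.
    """
    from .dosemap import scale_dose_to_time  # local import avoids cycle at import time

    if labels.unit != "label":
        raise ValueError("labels volume required")
    if labels.data.shape != dose.data.shape:
        raise ValueError("dose map and labels must share a grid")
    regions = regions if regions is not None else DEFAULT_REGIONS

    out = {}
    for name, codes in regions.items():
        mask = np.isin(labels.data, codes)
        if not mask.any():
            raise ValueError(f"region {name!r} (labels {codes}) is empty")
        out[name] = dose_metrics(dose, mask, x_list, v_thresholds, region=name,
                                 inclusive_vx=inclusive_vx)

    tn = None
    if "tumor" in out and "cortex" in out:
        tn = t_n_ratio(out["tumor"].mean_gy, out["cortex"].mean_gy)

    report = RegionDoseReport(out, t_n=tn, delivery=dose.delivery)
    if truncation_h is not None:
        actual_map = scale_dose_to_time(dose, truncation_h=truncation_h)
        report.actual = region_report(actual_map, labels, regions, x_list,
                                      v_thresholds, None, inclusive_vx)
    return report


def plot_dvh(curves: list[DVHCurve], path=None):
    """Plot cumulative DVH curves (one line per region)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ax.plot(c.bin_edges_gy, c.volume_fraction_pct, label=c.region or None)
    ax.set_xlabel("Dose (Gy)")
    ax.set_ylabel("Volume (%)")
    ax.set_ylim(0, 105)
    if any(c.region for c in curves):
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
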
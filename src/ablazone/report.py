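"""Per-zone reports, technique comparison, and group summaries.

``analyze`` runs either the segmentation-based analysis (technique A:
principal-axis diameters, shape ratios, Chebyshev-center inscribed sphere,
barycenter offset, treatable tumor sphere) or the plane-based standard
analysis (technique B) on a mask and returns a complete :class:`ZoneReport`.
``difference_ratio`` quantifies the disagreement of the two techniques'
inscribed-sphere diameters (A minus B, mm): a negative value means the
standard plane-based analysis overestimates the usable zone.
``summarize`` aggregates reports as mean, sample SD and range, the
conventional biomedical presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VolumeGrid
from . import geometry, chebyshev, standard
from .geometry import AxisDiameters, ShapeMetrics
from .chebyshev import InscribedSphere, TumorSphere

__all__ = [
    "ZoneReport",
    "GroupSummary",
    "analyze",
    "difference_ratio",
    "summarize",
]


@dataclass(frozen=True)
class ZoneReport:
    """Complete metric record of one treatment zone under one technique.

    Technique B reports carry the raw plane measurements and the unordered
    shape variant, but no Chebyshev center or barycenter offset (the
    plane-based workflow cannot localize the inscribed sphere).
    """

    technique: str
    margin_mm: float
    diameters: AxisDiameters
    shape: ShapeMetrics
    inscribed_diameter_mm: float
    tumor_diameter_mm: float
    chebyshev_center: np.ndarray | None = None
    barycenter_offset_mm: float | None = None
    raw_plane: dict | None = None
    shape_unordered: ShapeMetrics | None = None
    provenance: str | dict | None = None

    def __post_init__(self) -> None:
        if self.technique not in ("A", "B"):
            raise ValueError(f"technique must be 'A' or 'B', got {self.technique!r}")
        if self.technique == "B" and self.chebyshev_center is not None:
            raise ValueError("technique B cannot report a Chebyshev center")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "technique": self.technique,
            "margin_mm": self.margin_mm,
            "long_mm": self.diameters.long_mm,
            "intermediate_mm": self.diameters.intermediate_mm,
            "short_mm": self.diameters.short_mm,
            "directions": np.asarray(self.diameters.directions).tolist(),
            "barycenter": np.asarray(self.diameters.barycenter).tolist(),
            "circularity": self.shape.circularity,
            "sphericity": self.shape.sphericity,
            "inscribed_diameter_mm": self.inscribed_diameter_mm,
            "tumor_diameter_mm": self.tumor_diameter_mm,
            "chebyshev_center": (
                None if self.chebyshev_center is None else np.asarray(self.chebyshev_center).tolist()
            ),
            "barycenter_offset_mm": self.barycenter_offset_mm,
            "raw_plane": self.raw_plane,
            "shape_unordered": (
                None
                if self.shape_unordered is None
                else {
                    "circularity": self.shape_unordered.circularity,
                    "sphericity": self.shape_unordered.sphericity,
                }
            ),
            "provenance": self.provenance,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ZoneReport":
        diameters = AxisDiameters(
            d["long_mm"],
            d["intermediate_mm"],
            d["short_mm"],
            np.asarray(d["directions"], dtype=float),
            np.asarray(d["barycenter"], dtype=float),
        )
        su = d.get("shape_unordered")
        return cls(
            technique=d["technique"],
            margin_mm=d["margin_mm"],
            diameters=diameters,
            shape=ShapeMetrics(d["circularity"], d["sphericity"]),
            inscribed_diameter_mm=d["inscribed_diameter_mm"],
            tumor_diameter_mm=d["tumor_diameter_mm"],
            chebyshev_center=(
                None if d.get("chebyshev_center") is None else np.asarray(d["chebyshev_center"])
            ),
            barycenter_offset_mm=d.get("barycenter_offset_mm"),
            raw_plane=d.get("raw_plane"),
            shape_unordered=None if su is None else ShapeMetrics(su["circularity"], su["sphericity"]),
            provenance=d.get("provenance"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ZoneReport":
        return cls.from_dict(json.loads(text))

    def metrics(self) -> dict[str, float]:
        """Flat numeric metrics for tabulation (full precision)."""
        out = {
            "long_mm": self.diameters.long_mm,
            "intermediate_mm": self.diameters.intermediate_mm,
            "short_mm": self.diameters.short_mm,
            "circularity": self.shape.circularity,
            "sphericity": self.shape.sphericity,
            "inscribed_diameter_mm": self.inscribed_diameter_mm,
            "tumor_diameter_mm": self.tumor_diameter_mm,
        }
        if self.barycenter_offset_mm is not None:
            out["barycenter_offset_mm"] = self.barycenter_offset_mm
        return out

    def pretty(self) -> str:
        """Human-readable one-zone table: lengths to 0.1 mm, ratios to 0.01."""
        lines = [f"technique {self.technique} (margin {self.margin_mm:g} mm)"]
        for k, v in self.metrics().items():
            if k in ("circularity", "sphericity"):
                lines.append(f"  {k:24s} {v:.2f}")
            else:
                lines.append(f"  {k:24s} {v:.1f}")
        return "\n".join(lines)


def analyze(
    grid: VolumeGrid,
    technique: str = "A",
    margin_mm: float = 5.0,
    provenance: str | dict | None = None,
) -> ZoneReport:
    """Analyze one zone with the chosen technique; deterministic per mask."""
    if technique == "A":
        d = geometry.axis_diameters(grid)
        shape = ShapeMetrics.from_diameters(d)
        ins = chebyshev.largest_inscribed_sphere(grid, d.barycenter)
        tumor = chebyshev.treatable_tumor_sphere(ins, margin_mm)
        return ZoneReport(
            technique="A",
            margin_mm=float(margin_mm),
            diameters=d,
            shape=shape,
            inscribed_diameter_mm=ins.diameter_mm,
            tumor_diameter_mm=tumor.diameter_mm,
            chebyshev_center=ins.center,
            barycenter_offset_mm=ins.barycenter_offset_mm,
            provenance=provenance,
        )
    if technique == "B":
        rep = standard.technique_b_report(grid, margin_mm)
        return ZoneReport(
            technique="B",
            margin_mm=float(margin_mm),
            diameters=rep.ordered,
            shape=rep.shape,
            inscribed_diameter_mm=rep.inscribed_diameter_mm,
            tumor_diameter_mm=rep.tumor_diameter_mm,
            raw_plane={
                "axial_long_mm": rep.axial_long_mm,
                "axial_perp_mm": rep.axial_perp_mm,
                "craniocaudal_mm": rep.craniocaudal_mm,
            },
            shape_unordered=rep.shape_unordered,
            provenance=provenance,
        )
    raise ValueError(f"technique must be 'A' or 'B', got {technique!r}")


def difference_ratio(diameter_a_mm: float, diameter_b_mm: float) -> float:
    """Inscribed-sphere diameter difference, technique A minus technique B (mm).

    Negative: the standard plane-based analysis overestimates the zone;
    positive: it underestimates.
    """
    return float(diameter_a_mm) - float(diameter_b_mm)


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD and range per metric over a group of zone reports."""

    technique: str
    margin_mm: float
    n: int
    table: pd.DataFrame  # index: metric; columns: mean, sd, min, max

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def pretty(self) -> str:
        lines = [f"technique {self.technique}, n = {self.n}"]
        for m, row in self.table.iterrows():
            lines.append(
                f"  {m:24s} {row['mean']:7.1f} ± {row['sd']:5.1f}  "
                f"({row['min']:.1f} - {row['max']:.1f})"
            )
        return "\n".join(lines)


def summarize(reports: list[ZoneReport]) -> GroupSummary:
    """Aggregate reports of one technique as mean +/- sample SD and range.

    Uses the n-1 denominator; a single report yields SD 0 by convention
    (the n field flags it).
    """
    if not reports:
        raise ValueError("cannot summarize an empty report list")
    techniques = {r.technique for r in reports}
    margins = {r.margin_mm for r in reports}
    if len(techniques) > 1 or len(margins) > 1:
        raise ValueError(
            f"cannot mix techniques {sorted(techniques)} or margins {sorted(margins)} in one summary"
        )
    df = pd.DataFrame([r.metrics() for r in reports])
    table = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1).fillna(0.0) if len(df) > 1 else pd.Series(0.0, index=df.columns),
            "min": df.min(),
            "max": df.max(),
        }
    )
    return GroupSummary(
        technique=reports[0].technique,
        margin_mm=reports[0].margin_mm,
        n=len(reports),
        table=table,
    )
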
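"""End-to-end driver and reference-table summaries.

Two data routes live here:

* **fixture route** — a packaged transcription of the published LET/RBE_M
  tables (180 rows: 9 square fields × 5 off-axis positions × 4 water
  depths), with loaders, row invariants and the summary statistics behind
  the headline out-of-field claims;
* **pipeline route** — the synthetic chain (photon spectrum → Compton
  source → slowing-down fluences → LET moments → RBE_M prediction) run
  over the same geometry grid, for qualitative comparison against the
  fixture orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import moments, rbe, spectra
from .geometry import GeometryPoint
from .materials import StoppingPowerTable, build_table, default_energy_grid, _data_path

__all__ = [
    "CATEGORIES",
    "PublishedLETRecord",
    "SummaryReport",
    "position_category",
    "category_off_axis",
    "load_published_tables",
    "percent_increase",
    "summarize_out_of_field",
    "PipelineConfig",
    "run_pipeline",
    "PAPER_FIELDS_CM",
    "PAPER_DEPTHS_CM",
]

CATEGORIES = ("centre", "mid", "edge", "edge_plus_1", "edge_plus_2")
IN_FIELD = ("centre", "mid", "edge")
OUT_OF_FIELD = ("edge_plus_1", "edge_plus_2")

PAPER_FIELDS_CM = (0.7, 0.9, 1.8, 2.2, 2.7, 3.1, 3.6, 4.5, 10.0)
PAPER_DEPTHS_CM = (0.15, 1.35, 9.85, 19.9)


def category_off_axis(field_side_cm: float, category: str) -> float:
    """Off-axis distance (cm) of a named scoring position."""
    edge = field_side_cm / 2.0
    table = {
        "centre": 0.0,
        "mid": edge / 2.0,
        "edge": edge,
        "edge_plus_1": edge + 1.0,
        "edge_plus_2": edge + 2.0,
    }
    try:
        return table[category]
    except KeyError:
        raise ValueError(f"unknown category {category!r}") from None


def position_category(
    field_side_cm: float, off_axis_cm: float, atol_cm: float = 0.01
) -> str:
    """Classify an off-axis distance into the five scoring positions.

    Positions are the beam centre, half way to the edge, the edge
    (field_side/2), and 1 cm and 2 cm past the edge, matched with an
    absolute tolerance (default 0.01 cm).
    """
    if field_side_cm <= 0 or off_axis_cm < 0:
        raise ValueError("field side must be positive and off-axis non-negative")
    offsets = {c: category_off_axis(field_side_cm, c) for c in CATEGORIES}
    dists = {c: abs(off_axis_cm - v) for c, v in offsets.items()}
    best = min(dists, key=dists.get)
    if dists[best] > atol_cm:
        raise ValueError(
            f"off-axis {off_axis_cm} cm for a {field_side_cm} cm field matches no "
            f"scoring position (nearest: {best} at {offsets[best]} cm)"
        )
    return best


@dataclass(frozen=True)
class PublishedLETRecord:
    """One transcribed row of the reference LET/RBE_M tables."""

    field_cm: float
    depth_cm: float
    off_axis_cm: float
    position: str
    track_tef: float
    track_se: float
    dose_tef: float
    dose_se: float
    rbe_m: float
    rbe_u: float

    def __post_init__(self) -> None:
        if not self.dose_tef > self.track_tef:
            raise ValueError("dose-average TEF LET must exceed the track average")
        if not self.dose_se > self.track_se:
            raise ValueError("dose-average SE LET must exceed the track average")
        if self.rbe_m <= 0:
            raise ValueError("RBE_M must be positive")
        expected = position_category(self.field_cm, self.off_axis_cm)
        if expected != self.position:
            raise ValueError(
                f"position label {self.position!r} inconsistent with off-axis "
                f"{self.off_axis_cm} cm (expected {expected!r})"
            )


def load_published_tables(path=None) -> List[PublishedLETRecord]:
    """Load the packaged 180-row transcription of the reference tables."""
    path = path or _data_path("published_let_tables.csv")
    df = pd.read_csv(path, comment="#")
    required = {
        "field_cm", "depth_cm", "off_axis_cm", "position",
        "track_tef", "track_se", "dose_tef", "dose_se", "rbe_m", "rbe_u",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixture missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("fixture is empty")
    records = []
    for i, r in enumerate(df.itertuples(index=False)):
        try:
            records.append(PublishedLETRecord(*r))
        except ValueError as exc:
            raise ValueError(f"fixture row {i}: {exc}") from exc
    expected = len(PAPER_FIELDS_CM) * len(CATEGORIES) * len(PAPER_DEPTHS_CM)
    if len(records) != expected:
        raise ValueError(f"expected {expected} fixture rows, found {len(records)}")
    return records


def percent_increase(centre_value: float, edge2_value: float) -> float:
    """Percent change from the beam centre to 2 cm past the field edge."""
    if centre_value <= 0:
        raise ValueError("centre value must be positive")
    return 100.0 * (edge2_value - centre_value) / centre_value


@dataclass
class SummaryReport:
    """Out-of-field summary statistics over a set of LET/RBE records."""

    dose_tef_edge2_min: float
    dose_tef_edge2_max: float
    dose_se_edge2_min: float
    dose_se_edge2_max: float
    # per (depth, field): percent increase of dose_tef centre -> edge+2
    percent_increase_dose_tef: pd.DataFrame = field(repr=False, default=None)
    # per depth: max out-of-field RBE_M / min in-field RBE_M
    rbe_ratio_by_depth: dict = field(default_factory=dict)
    provenance: str = "fixture"

    def max_percent_increase_at(self, depth_cm: float) -> float:
        df = self.percent_increase_dose_tef
        return float(df.loc[df["depth_cm"] == depth_cm, "percent_increase"].max())


def _records_frame(records: Iterable) -> pd.DataFrame:
    rows = [
        {
            "field_cm": r.field_cm,
            "depth_cm": r.depth_cm,
            "position": r.position,
            "dose_tef": r.dose_tef,
            "dose_se": r.dose_se,
            "rbe_m": r.rbe_m,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def summarize_out_of_field(
    records: Sequence, provenance: str = "fixture"
) -> SummaryReport:
    """Out-of-field summary: edge+2 LET extrema, centre→edge+2 percent
    increases per field and depth, and RBE_M out/in ratios per depth.

    The in-field RBE_M reference is the minimum over the centre, mid and
    edge rows at each depth.
    """
    if not len(records):
        raise ValueError("no records to summarise")
    df = _records_frame(records)
    present = set(df["position"])
    needed = {"centre", "edge_plus_2"}
    if not needed <= present:
        raise ValueError(f"missing scoring positions: {sorted(needed - present)}")

    edge2 = df[df["position"] == "edge_plus_2"]
    centre = df[df["position"] == "centre"]

    merged = centre.merge(
        edge2, on=["field_cm", "depth_cm"], suffixes=("_centre", "_edge2")
    )
    merged["percent_increase"] = 100.0 * (
        merged["dose_tef_edge2"] - merged["dose_tef_centre"]
    ) / merged["dose_tef_centre"]

    in_field = df[df["position"].isin(IN_FIELD)]
    out_field = df[df["position"].isin(OUT_OF_FIELD)]
    rbe_ratio = {}
    for depth, grp in df.groupby("depth_cm"):
        lo = in_field[in_field["depth_cm"] == depth]["rbe_m"].min()
        hi = out_field[out_field["depth_cm"] == depth]["rbe_m"].max()
        rbe_ratio[float(depth)] = float(hi / lo)

    return SummaryReport(
        dose_tef_edge2_min=float(edge2["dose_tef"].min()),
        dose_tef_edge2_max=float(edge2["dose_tef"].max()),
        dose_se_edge2_min=float(edge2["dose_se"].min()),
        dose_se_edge2_max=float(edge2["dose_se"].max()),
        percent_increase_dose_tef=merged[
            ["field_cm", "depth_cm", "percent_increase"]
        ],
        rbe_ratio_by_depth=rbe_ratio,
        provenance=provenance,
    )


@dataclass
class PipelineConfig:
    """Configuration of one synthetic end-to-end run."""

    beam: spectra.PhotonBeamModel = field(default_factory=spectra.PhotonBeamModel)
    fields_cm: Sequence[float] = PAPER_FIELDS_CM
    depths_cm: Sequence[float] = PAPER_DEPTHS_CM
    categories: Sequence[str] = CATEGORIES
    delta_kev: float = 1.0
    grid_points: int = 200
    rbe_calibration_path: Optional[str] = None
    rbe_scale: str = "log10"
    rbe_weighted: bool = True
    rel_u: float = moments.DEFAULT_REL_U

    def geometries(self) -> List[GeometryPoint]:
        return [
            GeometryPoint(f, d, category_off_axis(f, c))
            for f in self.fields_cm
            for d in self.depths_cm
            for c in self.categories
        ]


def run_pipeline(
    config: PipelineConfig = None, table: StoppingPowerTable = None
) -> pd.DataFrame:
    """Run the synthetic chain over a geometry grid.

    Returns one row per geometry point with both LET moments for the TEF
    and SE spectra (keV/μm, Δ = config.delta_kev) and the predicted RBE_M
    at the spectrum's fluence-weighted mean photon energy.  Deterministic:
    identical configs yield identical frames.
    """
    config = config or PipelineConfig()
    if table is None:
        table = build_table(
            default_energy_grid(config.grid_points), config.delta_kev
        )
    cal = rbe.load_calibration(config.rbe_calibration_path)
    fit = rbe.fit_rbe_curve(cal, scale=config.rbe_scale, weighted=config.rbe_weighted)

    rows = []
    for geom in config.geometries():
        photon = spectra.generate_photon_spectrum(geom, config.beam)
        tef, se = spectra.generate_case(geom, config.beam, table)
        pred = rbe.predict_rbem(fit, rbe.effective_photon_energy(photon))
        rows.append(
            {
                "field_cm": geom.field_side_cm,
                "depth_cm": geom.depth_cm,
                "off_axis_cm": geom.off_axis_cm,
                "position": position_category(geom.field_side_cm, geom.off_axis_cm),
                "mean_photon_energy_mev": rbe.effective_photon_energy(photon),
                "track_tef": moments.track_average_let(tef, table),
                "track_se": moments.track_average_let(se, table),
                "dose_tef": moments.dose_average_let(tef, table),
                "dose_se": moments.dose_average_let(se, table),
                "rbe_m": pred.value,
                "rbe_u": pred.std_uncertainty,
                "rbe_extrapolated": pred.extrapolated,
                "rel_u": config.rel_u,
            }
        )
    return pd.DataFrame(rows)


def pipeline_records(df: pd.DataFrame) -> List[PublishedLETRecord]:
    """View pipeline output rows as records for ``summarize_out_of_field``."""
    return [
        PublishedLETRecord(
            field_cm=r.field_cm,
            depth_cm=r.depth_cm,
            off_axis_cm=r.off_axis_cm,
            position=r.position,
            track_tef=r.track_tef,
            track_se=r.track_se,
            dose_tef=r.dose_tef,
            dose_se=r.dose_se,
            rbe_m=r.rbe_m,
            rbe_u=r.rbe_u,
        )
        for r in df.itertuples(index=False)
    ]
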
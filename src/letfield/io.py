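"""Plain-text readers and writers for spectra and LET results.

Spectrum TSV dialect::

    # kind=TEF
    # delta_keV=1
    # field_cm=2.7  depth_cm=1.35  offaxis_cm=3.35
    # phi_at_delta=12.3
    E_low_MeV	E_high_MeV	fluence_density
    ...

LET results are emitted as CSV with one row per (geometry, kind).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .geometry import GeometryPoint
from .moments import FluenceSpectrum, LETResult

__all__ = ["write_spectrum_tsv", "read_spectrum_tsv", "results_to_frame", "write_results_csv"]


def write_spectrum_tsv(spec: FluenceSpectrum, path) -> None:
    lines = [f"# kind={spec.kind}", f"# delta_keV={spec.delta_kev:g}"]
    if spec.geometry is not None:
        g = spec.geometry
        lines.append(
            f"# field_cm={g.field_side_cm:g}  depth_cm={g.depth_cm:g}  "
            f"offaxis_cm={g.off_axis_cm:g}"
        )
    if spec.track_end_fluence is not None:
        lines.append(f"# phi_at_delta={spec.track_end_fluence:.10e}")
    lines.append("E_low_MeV\tE_high_MeV\tfluence_density")
    lo, hi = spec.bin_edges_mev[:-1], spec.bin_edges_mev[1:]
    for a, b, p in zip(lo, hi, spec.fluence_density):
        lines.append(f"{a:.10e}\t{b:.10e}\t{p:.10e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spectrum_tsv(path) -> FluenceSpectrum:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            if line.startswith("E_low"):
                continue
            rows.append([float(x) for x in line.split("\t")])
    if not rows:
        raise ValueError(f"no spectrum rows in {path}")
    arr = np.asarray(rows)
    lo, hi, phi = arr[:, 0], arr[:, 1], arr[:, 2]
    if not np.allclose(lo[1:], hi[:-1], rtol=1e-9):
        raise ValueError("bins are not contiguous")
    edges = np.concatenate([lo, hi[-1:]])
    geometry: Optional[GeometryPoint] = None
    if "field_cm" in meta:
        geometry = GeometryPoint(
            float(meta["field_cm"]), float(meta["depth_cm"]), float(meta["offaxis_cm"])
        )
    te = float(meta["phi_at_delta"]) if "phi_at_delta" in meta else None
    return FluenceSpectrum(
        bin_edges_mev=edges,
        fluence_density=phi,
        delta_kev=float(meta.get("delta_keV", 1.0)),
        kind=meta.get("kind", "TEF"),
        geometry=geometry,
        track_end_fluence=te,
    )


def results_to_frame(results: Iterable[LETResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        g = r.geometry
        rows.append(
            {
                "field_cm": g.field_side_cm if g else np.nan,
                "depth_cm": g.depth_cm if g else np.nan,
                "off_axis_cm": g.off_axis_cm if g else np.nan,
                "kind": r.kind,
                "L_track_keV_um": r.track_average_kev_um,
                "L_dose_keV_um": r.dose_average_kev_um,
                "delta_keV": r.delta_kev,
                "rel_u": r.relative_standard_uncertainty,
            }
        )
    return pd.DataFrame(rows)


def write_results_csv(results: Iterable[LETResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False)
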
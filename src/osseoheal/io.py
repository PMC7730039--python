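"""Output writers: legacy-ASCII VTK unstructured grids, CSV summaries, and
the run manifest.

Units in the emitted files follow the package convention (documented in the
VTK headers): coordinates mm, moduli MPa, fluid speeds um/s.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mechanoreg import HealingHistory, Phenotype

__all__ = ["write_vtk", "write_timeseries", "phenotype_codes"]

log = logging.getLogger("osseoheal")

_PHEN_CODE = {
    Phenotype.GRANULATION.value: 0,
    Phenotype.RESORPTION.value: 1,
    Phenotype.MATURE_BONE.value: 2,
    Phenotype.IMMATURE_BONE.value: 3,
    Phenotype.CARTILAGE.value: 4,
    Phenotype.FIBROUS_TISSUE.value: 5,
}
_REGION_CODE = {"implant": 0, "callus": 1, "cortical": 2, "cancellous": 3}


def phenotype_codes(phenotypes) -> np.ndarray:
    return np.array([_PHEN_CODE.get(p, -1) for p in phenotypes], dtype=int)


def write_vtk(mesh, path, cell_data: dict | None = None,
              point_data: dict | None = None,
              title: str = "osseoheal (mm, MPa, um/s)") -> None:
    """Write the mesh with cell/point arrays as a legacy-ASCII VTK file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.node_coords:
            fh.write(f"{x:.10g} {y:.10g} 0\n")
        E = mesh.n_elements
        fh.write(f"CELLS {E} {5 * E}\n")
        for conn in mesh.elements:
            fh.write("4 " + " ".join(str(int(n)) for n in conn) + "\n")
        fh.write(f"CELL_TYPES {E}\n")
        fh.write("\n".join(["9"] * E) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {E}\n")
            for name, arr in cell_data.items():
                _write_array(fh, name, np.asarray(arr))
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                _write_array(fh, name, np.asarray(arr))


def _write_array(fh, name, arr) -> None:
    if arr.ndim == 2:
        fh.write(f"VECTORS {name} double\n")
        for row in arr:
            z = row[2] if len(row) > 2 else 0.0
            fh.write(f"{row[0]:.10g} {row[1]:.10g} {z:.10g}\n")
        return
    kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
    fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
    fmt = "{:d}\n" if kind == "int" else "{:.10g}\n"
    for v in arr:
        fh.write(fmt.format(v))


def summary_frame(history: HealingHistory) -> pd.DataFrame:
    """Per-day class counts, BIC/BA with splits, mean modulus and stimulus."""
    rows = []
    for rec in history.days:
        counts = {f"n_{p.value}": int(np.sum(rec.phenotype == p.value))
                  for p in Phenotype}
        mm = rec.morphometry
        rows.append({
            "day": rec.day, **counts,
            "bic_percent": mm.bic_percent, "ba_percent": mm.ba_percent,
            "bic_mature": mm.bic_by_phenotype.get("mature_bone", 0.0),
            "bic_immature": mm.bic_by_phenotype.get("immature_bone", 0.0),
            "ba_mature": mm.ba_by_phenotype.get("mature_bone", 0.0),
            "ba_immature": mm.ba_by_phenotype.get("immature_bone", 0.0),
            "mean_modulus_mpa": rec.mean_modulus,
            "mean_stimulus": rec.mean_S,
        })
    return pd.DataFrame(rows)


def write_timeseries(history: HealingHistory, outdir) -> list[Path]:
    """One VTK frame per healing day plus a byte-stable CSV summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mesh = history.mesh
    cal = history.callus_elements
    region_code = np.array([_REGION_CODE.get(t, -1)
                            for t in mesh.element_region], dtype=int)
    written = []
    for rec in history.days:
        phen_full = np.full(mesh.n_elements, -1, dtype=int)
        phen_full[cal] = phenotype_codes(rec.phenotype)
        young = np.full(mesh.n_elements, np.nan)
        young[cal] = rec.young
        S = np.full(mesh.n_elements, np.nan)
        S[cal] = rec.S
        path = outdir / f"day_{rec.day:03d}.vtk"
        write_vtk(mesh, path,
                  cell_data={"region": region_code, "phenotype": phen_full,
                             "young_modulus_mpa": young, "stimulus": S},
                  point_data={"concentration": rec.concentration})
        written.append(path)

    df = summary_frame(history)
    csv_path = outdir / "summary.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g")
    written.append(csv_path)

    manifest = {
        "diffusivity_mm2_per_day": float(history.diffusivity),
        "days": len(history.days),
        "n_elements": int(mesh.n_elements),
        "n_callus_elements": int(len(cal)),
    }
    if history.config is not None:
        from .config import config_hash
        import dataclasses

        manifest["config"] = dataclasses.asdict(history.config)
        if isinstance(manifest["config"].get("domain_extent"), tuple):
            manifest["config"]["domain_extent"] = list(
                manifest["config"]["domain_extent"])
        manifest["config_hash"] = config_hash(history.config)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    written.append(outdir / "manifest.yaml")
    return written
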
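"""Plain-text import/export for the simulation artefacts.

All files are columnar tables with a JSON metadata header on lines starting
with ``#``; they round-trip through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (Chromosome, ChromosomePath, GenomeModel, Karyotype,
                       NucleusGeometry, LATTICE_STEP_UM)
from .irradiation import DoseGrid
from .repair import RejoinEvent
from .response import DoseResponseCurve


def _write_header(fh, meta: dict) -> None:
    fh.write("# " + json.dumps(meta) + "\n")


def _read_header(path) -> dict:
    with open(path) as fh:
        line = fh.readline()
    return json.loads(line.lstrip("# ").strip()) if line.startswith("#") else {}


# -- karyotype --------------------------------------------------------------

def write_karyotype(karyotype: Karyotype, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlength_bp\tcentromere_bp\n")
        for c in karyotype.chromosomes:
            fh.write(f"{c.id}\t{c.length_bp}\t{c.centromere_bp}\n")


def read_karyotype(path) -> Karyotype:
    df = pd.read_csv(path, sep="\t", comment="#")
    chroms = tuple(Chromosome(str(r.id), int(r.length_bp),
                              int(r.centromere_bp))
                   for r in df.itertuples())
    return Karyotype(chroms)


# -- genome model -----------------------------------------------------------

def write_genome(genome: GenomeModel, path) -> None:
    meta = {
        "semi_axes_um": list(genome.nucleus.semi_axes),
        "intermingling": genome.intermingling,
        "seed": genome.seed,
        "lattice_step_nm": LATTICE_STEP_UM * 1000,
        "karyotype": [[c.id, c.length_bp, c.centromere_bp]
                      for c in genome.karyotype.chromosomes],
        "domains": [[d.chromosome, list(d.center_um), list(d.semi_axes_um)]
                    for d in genome.domains],
    }
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("chromosome\tmonomer\tx_nm\ty_nm\tz_nm\n")
        for path_ in genome.paths:
            nm = path_.positions * 20
            for i, (x, y, z) in enumerate(nm):
                fh.write(f"{path_.chromosome}\t{i}\t{x}\t{y}\t{z}\n")


def read_genome(path) -> GenomeModel:
    from .geometry import ChromosomeDomain
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    nucleus = NucleusGeometry(*meta["semi_axes_um"])
    karyotype = Karyotype(tuple(
        Chromosome(cid, int(l), int(c)) for cid, l, c in meta["karyotype"]))
    domains = [ChromosomeDomain(cid, np.array(c), np.array(s),
                                scale=float(np.array(s)[0]
                                            / nucleus.semi_axes[0]))
               for cid, c, s in meta["domains"]]
    paths = []
    for chrom in karyotype.chromosomes:
        sub = df[df.chromosome == chrom.id]
        pos = (sub[["x_nm", "y_nm", "z_nm"]].to_numpy() // 20).astype(np.int32)
        paths.append(ChromosomePath(chrom.id, pos))
    return GenomeModel(nucleus, karyotype, domains, paths,
                       intermingling=bool(meta["intermingling"]),
                       seed=meta["seed"])


# -- dose grid --------------------------------------------------------------

def write_dose_grid(grid: DoseGrid, path, threshold_gy: float = 0.0) -> None:
    """Voxels above ``threshold_gy`` as (i, j, k, dose_Gy) rows.

    The dose is invariant along the beam axis, so one representative slab
    (k = 0) is written; the header records the axis and volume so the full
    3D map is implied.
    """
    meta = {
        "voxel_nm": 20,
        "beam_axis": grid.beam_axis,
        "volume_um": [grid.volume.side_x_um, grid.volume.side_y_um,
                      grid.volume.side_z_um],
        "prescribed_dose_gy": grid.prescribed_dose_gy,
        "mean_dose_gy": grid.mean_dose_gy,
        "note": "dose is constant along the beam axis; one slab written",
    }
    n0, n1 = grid.n_lateral
    ii, jj = np.nonzero(grid.lateral_dose_gy > threshold_gy)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("i\tj\tk\tdose_gy\n")
        for i, j in zip(ii - n0 // 2, jj - n1 // 2):
            d = grid.lateral_dose_gy[i + n0 // 2, j + n1 // 2]
            fh.write(f"{i}\t{j}\t0\t{d:.6g}\n")


# -- event log / curves -----------------------------------------------------

def write_events(events: list[RejoinEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("time_s\tend_a\tend_b\tkind\n")
        for ev in events:
            fh.write(f"{ev.time_s:.1f}\t{ev.end_a}\t{ev.end_b}\t{ev.kind}\n")


def write_curve(curve: DoseResponseCurve, path) -> None:
    with open(path, "w") as fh:
        _write_header(fh, {"category": curve.category,
                           "n_histories": curve.n_histories})
        fh.write("dose_gy\tyield\tse\n")
        for d, y, s in zip(curve.doses_gy, curve.yields, curve.std_errors):
            fh.write(f"{d:.6g}\t{y:.6g}\t{s:.6g}\n")


def read_curve(path) -> DoseResponseCurve:
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return DoseResponseCurve(
        category=meta.get("category", "unknown"),
        doses_gy=df["dose_gy"].to_numpy(),
        yields=df["yield"].to_numpy(),
        std_errors=df["se"].to_numpy(),
        n_histories=int(meta.get("n_histories", 0)))
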
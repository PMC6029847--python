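"""Plain-text readers and writers for the package's data classes.

All formats are TSV (or whitespace matrix text) with ``#``-prefixed metadata
header lines of the form ``# key: value``; writers mirror readers exactly so
round trips are lossless to float precision.  Topographies can additionally
be stored as single-channel TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .compression import CompressionTest, PhaseProtocol
from .exceptions import ValidationError
from .fibrilmorph import Topography
from .forcecurves import ElastoMap, ForceCurve

_FLOAT_FMT = "%.9g"


def _write_meta(handle, meta: dict):
    for key, value in meta.items():
        handle.write(f"# {key}: {value}\n")


def _read_meta(path: Path) -> tuple[dict, int]:
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta, n_header


def _parse_number(s, cast=float, default=None):
    try:
        return cast(s)
    except (TypeError, ValueError):
        return default


# -- force curves -----------------------------------------------------------

def write_force_curve(curve: ForceCurve, path):
    path = Path(path)
    with open(path, "w") as fh:
        _write_meta(
            fh,
            {
                "k_N_per_m": curve.k_n_per_m,
                "medium": curve.medium,
                "seed": curve.meta.get("seed", ""),
            },
        )
        fh.write("z_nm\tdeflection_nm\tsegment\n")
        for z, d, s in zip(curve.z_nm, curve.deflection_nm, curve.segments):
            fh.write(f"{z:.9g}\t{d:.9g}\t{s}\n")


def read_force_curve(path) -> ForceCurve:
    path = Path(path)
    meta, n_header = _read_meta(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    if "deflection_nm" in df.columns:
        defl = df["deflection_nm"].to_numpy()
        k = _parse_number(meta.get("k_N_per_m"))
        if k is None:
            raise ValidationError("force-curve file lacks a k_N_per_m header")
    elif "force_nN" in df.columns:
        k = _parse_number(meta.get("k_N_per_m"))
        if k is None:
            raise ValidationError("force column requires a k_N_per_m header")
        defl = df["force_nN"].to_numpy() / k
    else:
        raise ValidationError("curve file needs a deflection_nm or force_nN column")
    return ForceCurve(
        df["z_nm"].to_numpy(),
        defl,
        k,
        df["segment"].to_numpy(),
        medium=meta.get("medium", "hydrated"),
        meta={k2: v for k2, v in meta.items() if k2 not in ("k_N_per_m", "medium")},
    )


# -- topographies -----------------------------------------------------------

def write_topography(topo: Topography, path):
    """Matrix text (default) or single-channel TIFF by file suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(
            path,
            topo.heights_nm.astype(np.float32),
            description=json.dumps({"pixel_nm": topo.pixel_nm, "medium": topo.medium}),
        )
        return
    with open(path, "w") as fh:
        _write_meta(fh, {"pixel_nm": topo.pixel_nm, "medium": topo.medium})
        np.savetxt(fh, topo.heights_nm, fmt=_FLOAT_FMT)


def read_topography(path) -> Topography:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            heights = page.asarray().astype(float)
            desc = page.tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        return Topography(
            heights,
            float(meta.get("pixel_nm", 1.0)),
            medium=meta.get("medium", "hydrated"),
        )
    meta, n_header = _read_meta(path)
    heights = np.loadtxt(path, skiprows=n_header)
    return Topography(
        heights,
        _parse_number(meta.get("pixel_nm"), default=1.0),
        medium=meta.get("medium", "hydrated"),
    )


def write_mask(mask, path):
    np.savetxt(path, np.asarray(mask).astype(int), fmt="%d")


def read_mask(path) -> np.ndarray:
    return np.loadtxt(path).astype(bool)


# -- compression traces -----------------------------------------------------

def write_compression_test(test: CompressionTest, path):
    path = Path(path)
    with open(path, "w") as fh:
        _write_meta(
            fh,
            {
                "R_h_um": test.r_h_um,
                "R_v_um": test.r_v_um,
                "d0_um": test.d0_um,
                "n_cycles": test.protocol.n_cycles,
                "phases_s": f"{test.protocol.compress_s},{test.protocol.hold_s},"
                f"{test.protocol.recover_s},{test.protocol.rest_s}",
            },
        )
        fh.write("time_s\tforce_uN\tdisplacement_um\n")
        for t, f, d in zip(test.time_s, test.force_un, test.displacement_um):
            fh.write(f"{t:.9g}\t{f:.9g}\t{d:.9g}\n")


def read_compression_test(path) -> CompressionTest:
    path = Path(path)
    meta, n_header = _read_meta(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    protocol = PhaseProtocol()
    if "phases_s" in meta:
        c, h, r, s = (float(v) for v in meta["phases_s"].split(","))
        protocol = PhaseProtocol(
            c, h, r, s, n_cycles=_parse_number(meta.get("n_cycles"), int, 5)
        )
    return CompressionTest(
        df["time_s"].to_numpy(),
        df["force_uN"].to_numpy(),
        df["displacement_um"].to_numpy(),
        _parse_number(meta.get("R_h_um")),
        _parse_number(meta.get("R_v_um")),
        _parse_number(meta.get("d0_um")),
        protocol=protocol,
    )


# -- elastographs and tables ------------------------------------------------

def write_elastomap(emap: ElastoMap, path):
    pd.DataFrame(
        {
            "x_um": emap.x_um.ravel(),
            "y_um": emap.y_um.ravel(),
            "modulus_kPa": emap.modulus_kpa.ravel(),
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_elastomap(path, donor: str = "", site: str = "") -> ElastoMap:
    df = pd.read_csv(path, sep="\t")
    return ElastoMap(
        df["x_um"].to_numpy(), df["y_um"].to_numpy(), df["modulus_kPa"].to_numpy(),
        donor=donor, site=site,
    )


def read_table(path) -> pd.DataFrame:
    """CSV or TSV table by suffix (``#`` comment lines allowed)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#")


def write_table(df: pd.DataFrame, path):
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
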
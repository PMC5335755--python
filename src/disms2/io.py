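"""Reading and writing peak lists, distance matrices and trees.

MGF is the canonical text format here (read and written through
pyteomics); mzML 1.1 is read with a small lxml-based reader covering the
subset this package needs -- MS level, 32/64-bit float binary arrays with
zlib or no compression, selected ion m/z, charge state, and scan start
time (minutes converted to seconds). Spectra with zero peaks are retained
at parse time; preprocessing excludes them later, keeping I/O lossless.
"""

from __future__ import annotations

import base64
import re
import warnings
import zlib
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .matching import DistanceMatrix
from .spectra import Run, Spectrum

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "write_distance_matrix",
    "read_distance_matrix",
    "read_annotation_table",
    "read_groups",
]

_SCAN_IN_TITLE = re.compile(r"scan[=\s:._]*(\d+)", re.IGNORECASE)


def _scan_number(params: dict, block_index: int) -> int:
    scans = params.get("scans")
    if scans is not None:
        try:
            return int(str(scans).split("-")[0])
        except ValueError:
            pass
    title = params.get("title", "")
    m = _SCAN_IN_TITLE.search(str(title))
    if m:
        return int(m.group(1))
    return block_index  # 1-based block order fallback


def read_mgf(path: Union[str, Path]) -> Run:
    """Read an MGF peak-list file into a :class:`Run`.

    CHARGE ``2+`` parses to 2; a block without CHARGE yields an unknown
    charge. Scan numbers come from SCANS, then from a ``scan=N`` pattern
    in TITLE, then from block order. Peaks are sorted ascending by m/z.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    spectra = []
    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for block_index, entry in enumerate(reader, start=1):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(
                    f"{path.name}: block {block_index} has no PEPMASS")
            charge = params.get("charge")
            charge = int(charge[0]) if charge else None
            rt = params.get("rtinseconds")
            spectra.append(Spectrum(
                scan_number=_scan_number(params, block_index),
                precursor_mz=float(pepmass[0]),
                precursor_charge=charge,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                retention_time=float(rt) if rt is not None else None,
            ))
    return Run(run_id=path.stem, spectra=spectra)


def write_mgf(run: Run, path: Union[str, Path]) -> None:
    """Write a run as MGF (full float precision, round-trip safe)."""
    entries = []
    for s in run:
        params = {
            "title": f"{run.run_id} scan={s.scan_number}",
            "pepmass": s.precursor_mz,
            "scans": s.scan_number,
        }
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time
        entries.append({
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": params,
        })
    with open(path, "w") as fh:
        _mgf.write(entries, fh)


# --- mzML ----------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _decode_binary_array(bda) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    for cv in bda.iter(f"{{{_MZML_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000521":          # 32-bit float
            dtype = "<f4"
        elif acc == "MS:1000523":        # 64-bit float
            dtype = "<f8"
        elif acc == "MS:1000574":        # zlib compression
            compressed = True
    node = bda.find(f"{{{_MZML_NS}}}binary")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _array_kind(bda) -> Optional[str]:
    for cv in bda.iter(f"{{{_MZML_NS}}}cvParam"):
        if cv.get("accession") == "MS:1000514":
            return "mz"
        if cv.get("accession") == "MS:1000515":
            return "intensity"
    return None


def read_mzml(path: Union[str, Path]) -> Run:
    """Read the MS2 spectra of an mzML 1.1 file into a :class:`Run`.

    MS1 (and higher-level) spectra are skipped. A file without any MS2
    spectra produces a warning and an empty run.
    """
    from lxml import etree

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    spectra = []
    block_index = 0
    for _, elem in etree.iterparse(str(path), tag=f"{{{_MZML_NS}}}spectrum"):
        block_index += 1
        ms_level = None
        for cv in elem.findall(f"{{{_MZML_NS}}}cvParam"):
            if cv.get("accession") == "MS:1000511":
                ms_level = int(cv.get("value"))
        if ms_level != 2:
            elem.clear()
            continue
        mz = intensity = None
        for bda in elem.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            kind = _array_kind(bda)
            if kind == "mz":
                mz = _decode_binary_array(bda)
            elif kind == "intensity":
                intensity = _decode_binary_array(bda)
        prec_mz, charge = None, None
        for cv in elem.iter(f"{{{_MZML_NS}}}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000744":
                prec_mz = float(cv.get("value"))
            elif acc == "MS:1000041":
                charge = int(cv.get("value"))
        rt = None
        for scan in elem.iter(f"{{{_MZML_NS}}}scan"):
            for cv in scan.findall(f"{{{_MZML_NS}}}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitName") == "minute":
                        rt *= 60.0
        if prec_mz is None:
            raise ValueError(
                f"{path.name}: MS2 spectrum {elem.get('id')!r} lacks a "
                f"selected ion m/z")
        m = re.search(r"scan=(\d+)", elem.get("id") or "")
        spectra.append(Spectrum(
            scan_number=int(m.group(1)) if m else block_index,
            precursor_mz=prec_mz,
            precursor_charge=charge,
            mz=mz if mz is not None else np.empty(0),
            intensity=intensity if intensity is not None else np.empty(0),
            retention_time=rt,
        ))
        elem.clear()
    if not spectra:
        warnings.warn(f"{path.name}: no MS2 spectra found; returning empty run")
    return Run(run_id=path.stem, spectra=spectra)


# --- tables --------------------------------------------------------------

def write_distance_matrix(matrix: DistanceMatrix, path: Union[str, Path]) -> None:
    """Write a distance matrix as a labelled square TSV."""
    matrix.to_dataframe().to_csv(path, sep="\t")


def read_distance_matrix(path: Union[str, Path]) -> DistanceMatrix:
    """Read a labelled square TSV distance matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return DistanceMatrix([str(c) for c in df.columns], df.to_numpy(dtype=float))


def read_annotation_table(path: Union[str, Path]):
    """Read a PSM table (TSV: run_id, scan_number, peptide)."""
    from .modes import AnnotationTable
    return AnnotationTable.from_tsv(path)


def read_groups(path: Union[str, Path]) -> dict:
    """Read a group-label table (TSV: run_id, group) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("groups table needs columns run_id and group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
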
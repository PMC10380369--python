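"""Spectrum container and standard MS format I/O (MGF, mzML, TSV reports).

MGF parsing and writing are delegated to pyteomics.  mzML is read by a
compact built-in reader (element tree + controlled-vocabulary
accessions) covering the subset the pipeline needs: centroided MS2
scans with 32/64-bit float peak arrays, optionally zlib-compressed.
"""

from __future__ import annotations

import base64
import os
import struct
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from pyteomics import mgf as _mgf

__all__ = ["Peak", "Spectrum", "read_mgf", "write_mgf", "read_mzml",
           "write_report", "read_report", "REPORT_COLUMNS"]


@dataclass(frozen=True)
class Peak:
    """A centroided peak: m/z (Da, > 0) and non-negative intensity."""

    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum with its precursor ion.

    ``ions`` optionally lists additional precursor-level ion observations
    of the same analyte, as ``(polarity, m/z)`` pairs — e.g. the [M-H]-
    and [M+HCOO]- ions seen in the negative-mode survey scan.  They are
    used to corroborate the neutral mass during annotation.
    """

    id: str
    precursor_mz: float
    polarity: str = "positive"
    rt: Optional[float] = None  # minutes
    peaks: List[Peak] = field(default_factory=list)
    precursor_species: Optional[str] = None
    sample_part: Optional[str] = None  # leaf | stem | root
    ions: List[Tuple[str, float]] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mzs(self) -> List[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> List[float]:
        return [p.intensity for p in self.peaks]

    def all_ions(self) -> List[Tuple[str, float]]:
        """Precursor plus any auxiliary ions, deduplicated."""
        out = [(self.polarity, self.precursor_mz)]
        for pol, mz in self.ions:
            if (pol, mz) not in out:
                out.append((pol, mz))
        return out


def _ions_to_mgf_field(ions: Sequence[Tuple[str, float]]) -> str:
    return ";".join(f"{pol}:{mz:.5f}" for pol, mz in ions)


def _ions_from_mgf_field(text: str) -> List[Tuple[str, float]]:
    out = []
    for tok in str(text).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        pol, mz = tok.split(":")
        out.append((pol, float(mz)))
    return out


def read_mgf(path: str | os.PathLike) -> List[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Polarity is inferred from the CHARGE sign; RTINSECONDS is converted
    to minutes.  A malformed block raises ValueError naming its index.
    """
    spectra: List[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            try:
                params = entry["params"]
                pepmass = params["pepmass"]
                prec = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                charges = params.get("charge")
                polarity = "positive"
                if charges:
                    polarity = "positive" if int(charges[0]) > 0 else "negative"
                rt = params.get("rtinseconds")
                rt_min = float(rt) / 60.0 if rt is not None else None
                peaks = [Peak(float(mz), float(inten))
                         for mz, inten in zip(entry["m/z array"], entry["intensity array"])]
                spec = Spectrum(
                    id=str(params.get("title", f"scan_{i}")),
                    precursor_mz=prec,
                    polarity=polarity,
                    rt=rt_min,
                    peaks=peaks,
                    precursor_species=params.get("species"),
                    sample_part=params.get("part"),
                    ions=_ions_from_mgf_field(params.get("ions", "")),
                )
            except Exception as exc:
                raise ValueError(f"malformed MGF block {i} in {path}: {exc}") from exc
            spectra.append(spec)
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | os.PathLike) -> None:
    """Write spectra to MGF (the exchange format of the generator)."""
    entries = []
    for s in spectra:
        params = {
            "title": s.id,
            "pepmass": s.precursor_mz,
            "charge": "1+" if s.polarity == "positive" else "1-",
        }
        if s.rt is not None:
            params["rtinseconds"] = s.rt * 60.0
        if s.precursor_species:
            params["species"] = s.precursor_species
        if s.sample_part:
            params["part"] = s.sample_part
        if s.ions:
            params["ions"] = _ions_to_mgf_field(s.ions)
        entries.append({
            "params": params,
            "m/z array": s.mzs,
            "intensity array": s.intensities,
        })
    # scientific notation keeps relative intensity precision on re-read
    _mgf.write(entries, str(path), file_mode="w", fragment_format="{:.6f} {:.8e}")


# mzML controlled-vocabulary accessions used by the reader
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_NEGATIVE = "MS:1000129"
_CV_SELECTED_MZ = "MS:1000744"
_CV_SCAN_START = "MS:1000016"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"


def _cv(elem) -> Dict[str, str]:
    """accession -> value for all cvParam descendants of an element."""
    return {c.get("accession"): c.get("value", "")
            for c in elem.iter() if c.tag.endswith("cvParam")}


def _decode_binary_array(array_elem) -> List[float]:
    params = _cv(array_elem)
    binary = array_elem.find("{*}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _CV_ZLIB in params:
        raw = zlib.decompress(raw)
    fmt = "f" if _CV_F32 in params else "d"
    width = 4 if fmt == "f" else 8
    return list(struct.unpack(f"<{len(raw) // width}{fmt}", raw))


def read_mzml(path: str | os.PathLike) -> List[Spectrum]:
    """Read centroided MS2 scans from an mzML file; MS1 scans are ignored.

    Supports 32/64-bit float peak arrays with optional zlib compression.
    Profile-mode MS2 spectra raise ValueError ("centroid required").
    """
    spectra: List[Spectrum] = []
    for _, elem in ET.iterparse(str(path)):
        if elem.tag.split("}")[-1] != "spectrum" or elem.find("{*}binaryDataArrayList") is None:
            continue
        top = {c.get("accession"): c.get("value", "")
               for c in elem.findall("{*}cvParam")}
        if int(top.get(_CV_MS_LEVEL, 1)) != 2:
            elem.clear()
            continue
        sid = elem.get("id", f"scan_{len(spectra)}")
        if _CV_PROFILE in top and _CV_CENTROID not in top:
            raise ValueError(f"centroid required: spectrum {sid} in {path} is profile mode")
        sel = elem.find("{*}precursorList/{*}precursor/{*}selectedIonList/{*}selectedIon")
        if sel is None:
            raise ValueError(f"mzML MS2 spectrum {sid} lacks a selected ion")
        prec_mz = float(_cv(sel)[_CV_SELECTED_MZ])
        polarity = "negative" if _CV_NEGATIVE in top else "positive"
        rt = None
        scan = elem.find("{*}scanList/{*}scan")
        if scan is not None:
            scan_params = {c.get("accession"): c for c in scan.findall("{*}cvParam")}
            if _CV_SCAN_START in scan_params:
                c = scan_params[_CV_SCAN_START]
                rt = float(c.get("value"))
                if c.get("unitName", "minute") in ("second", "seconds"):
                    rt /= 60.0
        mzs: List[float] = []
        intensities: List[float] = []
        for array_elem in elem.findall("{*}binaryDataArrayList/{*}binaryDataArray"):
            params = _cv(array_elem)
            if _CV_MZ_ARRAY in params:
                mzs = _decode_binary_array(array_elem)
            elif _CV_INTENSITY_ARRAY in params:
                intensities = _decode_binary_array(array_elem)
        peaks = [Peak(mz, inten) for mz, inten in zip(mzs, intensities)]
        spectra.append(Spectrum(id=sid, precursor_mz=prec_mz, polarity=polarity,
                                rt=rt, peaks=peaks))
        elem.clear()
    return spectra


REPORT_COLUMNS = [
    "spectrum_id", "aglycone", "n_glc", "n_ara", "skeleton", "neutral_mass",
    "species", "ppm", "matched_fragments", "score", "sample_part",
]


def write_report(annotations, path: str | os.PathLike, header_lines: Sequence[str] = ()) -> None:
    """Write a tab-separated annotation report (one row per annotation).

    ``header_lines`` are written first as '#'-prefixed provenance comments.
    """
    rows = []
    for a in annotations:
        rows.append({
            "spectrum_id": a.spectrum_id,
            "aglycone": a.aglycone,
            "n_glc": a.glycan.n_glc,
            "n_ara": a.glycan.n_ara,
            "skeleton": a.skeleton,
            "neutral_mass": round(a.neutral_mass, 4),
            "species": a.species,
            "ppm": round(a.ppm, 1),
            "matched_fragments": len(a.matched_fragments),
            "score": round(a.score, 3),
            "sample_part": a.sample_part if a.sample_part is not None else "",
        })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t", comment="#")
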
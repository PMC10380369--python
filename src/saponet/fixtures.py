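"""Packaged reference dataset: 41 steroidal saponins of Smilax sieboldii.

The TSV shipped under ``saponet/data`` transcribes, row by row, the
published UHPLC-QToF characterization of the leaf, stem and root/rhizome
extracts: per analyte the molecular formula, retention time, observed and
calculated ion-species m/z with their signed ppm errors, the positive-mode
fragment ions with their neutral-loss labels, and the plant-part
detection calls (+ / ++ / t / ND).  Isobaric isomers are stored as
continuation records that inherit the group leader's ions and fragments.

``load_fixtures`` materializes the inheritance and returns 41 fully
populated records; ``fixture_spectrum`` converts a record into the
:class:`~saponet.spectra.Spectrum` the annotation pipeline consumes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .masses import ADDUCTS, parse_formula, Formula
from .spectra import Peak, Spectrum

__all__ = ["IonEntry", "FixtureRecord", "load_fixtures", "fixture_spectrum",
           "data_path", "N_RECORDS"]

N_RECORDS = 41


@dataclass(frozen=True)
class IonEntry:
    """One precursor-level ion observation: species, observed m/z, and the
    calculated m/z / signed ppm as printed in the source table."""

    adduct: str
    observed_mz: float
    printed_calc_mz: float
    printed_ppm: float
    major: bool = False

    @property
    def polarity(self) -> str:
        return ADDUCTS[self.adduct].polarity


@dataclass
class FixtureRecord:
    number: int
    group: int
    name: str
    formula: Formula
    rt: float
    parts: Dict[str, str]  # leaf/stem/root -> + | ++ | t | ND
    ions: List[IonEntry] = field(default_factory=list)
    fragments: List[Tuple[float, str]] = field(default_factory=list)  # (m/z, loss label)
    # the published structural assignment, used as ground truth in tests
    aglycone: str = ""
    n_glc: int = 0
    n_ara: int = 0
    extra_water: int = 0

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass

    @property
    def primary_positive_ion(self) -> Optional[IonEntry]:
        for ion in self.ions:
            if ion.polarity == "positive":
                return ion
        return None


def data_path(name: str):
    """Path-like handle to a packaged data file."""
    return importlib.resources.files("saponet").joinpath("data", name)


def load_fixtures() -> List[FixtureRecord]:
    """Load and materialize the 41 reference records.

    Raises ValueError if the record count does not match the checksum
    header (guards against transcription drift).
    """
    declared = None
    raw: Dict[int, FixtureRecord] = {}
    own_fragments: Dict[int, List[Tuple[float, str]]] = {}
    own_ions: Dict[int, List[IonEntry]] = {}

    text = data_path("sieboldii_reference.tsv").read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            cells = line[1:].strip().split("\t")
            if cells[0] == "records":
                declared = int(cells[1])
            continue
        cells = line.rstrip("\n").split("\t")
        kind = cells[0]
        if kind == "C":
            (no, group, rt, formula, name, aglycone,
             n_glc, n_ara, extra_water, leaf, stem, root) = cells[1:13]
            no = int(no)
            raw[no] = FixtureRecord(
                number=no, group=int(group), rt=float(rt),
                formula=parse_formula(formula),
                name="" if name == "-" else name,
                parts={"leaf": leaf, "stem": stem, "root": root},
                aglycone=aglycone, n_glc=int(n_glc), n_ara=int(n_ara),
                extra_water=int(extra_water),
            )
        elif kind == "I":
            no = int(cells[1])
            adduct = cells[2]
            if adduct not in ADDUCTS:
                raise ValueError(f"line {lineno}: unknown ion species {adduct!r}")
            own_ions.setdefault(no, []).append(IonEntry(
                adduct=adduct, observed_mz=float(cells[3]),
                printed_calc_mz=float(cells[4]), printed_ppm=float(cells[5]),
                major=cells[6] == "1"))
        elif kind == "F":
            no = int(cells[1])
            own_fragments.setdefault(no, []).append((float(cells[2]), cells[3]))
        else:
            raise ValueError(f"line {lineno}: unknown line type {kind!r}")

    if declared is None or declared != len(raw):
        raise ValueError(
            f"fixture checksum mismatch: declared {declared}, parsed {len(raw)} records")

    records: List[FixtureRecord] = []
    for no in sorted(raw):
        rec = raw[no]
        leader = raw[rec.group]
        ions = list(own_ions.get(rec.group, [])) if rec.group != no else []
        ions += own_ions.get(no, [])
        rec.ions = ions
        rec.fragments = own_fragments.get(no) or list(own_fragments.get(rec.group, []))
        if not rec.name:
            rec.name = leader.name
        records.append(rec)
    return records


def fixture_spectrum(record: FixtureRecord) -> Spectrum:
    """Build the positive-mode MS/MS spectrum of a reference record.

    Fragment intensities are uniform (the source table prints none); the
    observed primary positive ion is included as a peak, and all ion
    observations are carried for neutral-mass corroboration.
    """
    primary = record.primary_positive_ion
    if primary is None:
        raise ValueError(f"record {record.number} has no positive-mode ion")
    mzs = [mz for mz, _ in record.fragments]
    if not any(abs(mz - primary.observed_mz) < 1e-6 for mz in mzs):
        mzs.append(primary.observed_mz)
    return Spectrum(
        id=f"ref{record.number:02d}",
        precursor_mz=primary.observed_mz,
        polarity="positive",
        rt=record.rt,
        peaks=[Peak(mz, 1.0) for mz in sorted(mzs)],
        precursor_species=primary.adduct,
        ions=[(ion.polarity, ion.observed_mz) for ion in record.ions],
        metadata={"compound_no": record.number, "name": record.name},
    )
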
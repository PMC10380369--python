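"""Neutral-loss dereplication of steroidal saponins.

The central computation: explain an observed precursor (or a set of
coherent ion species) as *sapogenin backbone + n×glucosyl + m×arabinosyl
(+ one extra water for the furostane hemiketal)*, predict the cohesive
fragment ladder that such a glycoside produces at high collision energy,
match it against the MS/MS peaks, and classify the skeleton as furostane
or (iso)spirostane from the ion-species evidence.

Scientific conventions encoded here:

* Sugars are reported as a composition (counts of Glc and Ara), never a
  sequence or linkage — tandem MS cannot order losses of identical
  residues, and positional isomers share spectra.
* Furostanes (open F-ring, labile C-22 OH) carry one extra water in the
  molecular formula and ionize as [M+H-H2O]+; (iso)spirostanes (closed
  ketal) ionize intact.  This is also the skeleton classification rule.
* The E/F-ring retro-cleavage of the sapogenin core loses C8H16O2
  (144.1150) for CH3-substituted side chains and C8H14O2 (142.0994,
  optionally with additional water, i.e. the quoted 160 Da) for the
  27-hydroxylated series.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .masses import (ADDUCTS, Formula, adduct_mz, neutral_loss_mass,
                     parse_formula, ppm_error)
from .spectra import Peak, Spectrum

__all__ = [
    "AglyconeDef", "load_aglycone_library", "default_aglycones",
    "GlycanComposition", "MassCandidate", "infer_neutral_mass",
    "Candidate", "decompose_mass", "LadderIon", "generate_ladder",
    "parse_loss_label", "FragmentMatch", "match_ladder",
    "classify_skeleton", "Annotation", "AnnotationConfig", "annotate",
    "FUROSTANE", "SPIROSTANE", "AMBIGUOUS",
]

FUROSTANE = "furostane"
SPIROSTANE = "(iso)spirostane"
AMBIGUOUS = "ambiguous"

#: water mass, used for the furostane hemiketal hydrate
_W = neutral_loss_mass("H2O")


@dataclass(frozen=True)
class AglyconeDef:
    """A sapogenin backbone class of the search space."""

    name: str
    formula: Formula
    ef_loss: str  # "EF144" | "EF142"
    max_water_losses: int = 4
    nominal_mh: int = 0  # nominal [M+H]+ anchor, informational

    @property
    def mass(self) -> float:
        return self.formula.mass


_DEFAULT_AGLYCONES: Optional[List[AglyconeDef]] = None


def load_aglycone_library(path) -> List[AglyconeDef]:
    """Read a backbone library TSV (name / formula / nominal_mh / ef_loss /
    max_water_losses); '#' lines are comments."""
    defs: List[AglyconeDef] = []
    text = path.read_text() if hasattr(path, "read_text") else open(path).read()
    header: Optional[List[str]] = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = cells
            continue
        row = dict(zip(header, cells))
        defs.append(AglyconeDef(
            name=row["name"],
            formula=parse_formula(row["formula"]),
            ef_loss=row["ef_loss"],
            max_water_losses=int(row["max_water_losses"]),
            nominal_mh=int(row["nominal_mh"]),
        ))
    if not defs:
        raise ValueError(f"empty aglycone library: {path}")
    return defs


def default_aglycones() -> List[AglyconeDef]:
    """The six packaged backbone classes (diosgenin, laxogenin,
    sarsa/tigogenin, and their 27-/6-oxygenated variants)."""
    global _DEFAULT_AGLYCONES
    if _DEFAULT_AGLYCONES is None:
        from .fixtures import data_path
        _DEFAULT_AGLYCONES = load_aglycone_library(data_path("aglycones.tsv"))
    return list(_DEFAULT_AGLYCONES)


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of glucosyl and arabinosyl residues; (0, 0) is a free sapogenin."""

    n_glc: int = 0
    n_ara: int = 0

    def __post_init__(self) -> None:
        if self.n_glc < 0 or self.n_ara < 0:
            raise ValueError("residue counts must be non-negative")

    @property
    def residue_mass(self) -> float:
        return self.n_glc * neutral_loss_mass("Glc") + self.n_ara * neutral_loss_mass("Ara")


# ---------------------------------------------------------------------------
# neutral-mass inference from coherent ion species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassCandidate:
    """A neutral-mass hypothesis with its per-ion species assignments."""

    mass: float
    assignments: Tuple[Tuple[int, str, float], ...]  # (ion index, species, implied mass)

    @property
    def support(self) -> int:
        return len(self.assignments)

    def species_of(self, ion_index: int) -> Optional[str]:
        for idx, species, _ in self.assignments:
            if idx == ion_index:
                return species
        return None


def infer_neutral_mass(ions: Sequence[Tuple[str, float]],
                       tol_ppm: float = 5.0) -> List[MassCandidate]:
    """Neutral-mass candidates explaining a set of (polarity, m/z) ions.

    Every ion is tried against every known species of its polarity; the
    implied neutral masses are clustered within ``tol_ppm`` and candidates
    explained by more ions rank first.  Returns an empty list when no ion
    matches any species (cannot happen with the standard seven adducts,
    which cover every polarity) rather than raising.
    """
    if not ions:
        raise ValueError("at least one ion is required")
    implied: List[Tuple[float, int, str]] = []
    for idx, (polarity, mz) in enumerate(ions):
        for name, spec in ADDUCTS.items():
            if spec.polarity != polarity:
                continue
            m = spec.neutral_mass(mz)
            if m > 0:
                implied.append((m, idx, name))

    seen: Dict[frozenset, MassCandidate] = {}
    for anchor, _, _ in implied:
        tol = tol_ppm * 1e-6 * anchor
        chosen: Dict[int, Tuple[float, str]] = {}
        for m, idx, name in implied:
            if abs(m - anchor) <= tol:
                if idx not in chosen or abs(m - anchor) < abs(chosen[idx][0] - anchor):
                    chosen[idx] = (m, name)
        key = frozenset((idx, name) for idx, (_, name) in chosen.items())
        consensus = statistics.median(m for m, _ in chosen.values())
        cand = MassCandidate(
            mass=consensus,
            assignments=tuple(sorted((idx, name, m) for idx, (m, name) in chosen.items())),
        )
        prev = seen.get(key)
        if prev is None or cand.support > prev.support:
            seen[key] = cand
    return sorted(seen.values(), key=lambda c: (-c.support, c.mass))


# ---------------------------------------------------------------------------
# mass decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """One decomposition of a neutral mass: backbone + glycan (+ hydrate)."""

    aglycone: AglyconeDef
    glycan: GlycanComposition
    extra_water: int  # 1 for the furostane 22-OH hydrate
    theoretical_mass: float
    ppm: float  # signed, theoretical vs the queried mass

    @property
    def skeleton(self) -> str:
        return FUROSTANE if self.extra_water else SPIROSTANE


def decompose_mass(mass: float, tol_ppm: float = 5.0,
                   aglycones: Optional[Sequence[AglyconeDef]] = None,
                   max_glc: int = 4, max_ara: int = 2,
                   allow_extra_water: bool = True) -> List[Candidate]:
    """All (backbone, n_glc, n_ara, extra_water) combinations whose exact
    mass lies within ``tol_ppm`` of ``mass``, sorted by |ppm|.

    The search is an exhaustive enumeration of the configured grid; an
    empty list means the mass is not explainable as a saponin of the
    library.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if aglycones is None:
        aglycones = default_aglycones()
    out: List[Candidate] = []
    for agl in aglycones:
        for n_glc in range(max_glc + 1):
            for n_ara in range(max_ara + 1):
                for water in range(2 if allow_extra_water else 1):
                    glycan = GlycanComposition(n_glc, n_ara)
                    theo = agl.mass + glycan.residue_mass + water * _W
                    ppm = ppm_error(theo, mass)
                    if abs(ppm) <= tol_ppm:
                        out.append(Candidate(agl, glycan, water, theo, ppm))
    out.sort(key=lambda c: (abs(c.ppm), c.aglycone.name, c.extra_water))
    return out


# ---------------------------------------------------------------------------
# fragment ladder
# ---------------------------------------------------------------------------

_LOSS_ALIASES = {
    "H2O": "H2O", "Glc": "Glc", "Ara": "Ara",
    "C8H16O2": "EF144", "C8H14O2": "EF142", "C8H16O3": "EF160",
    "EF144": "EF144", "EF142": "EF142", "EF160": "EF160",
}


def parse_loss_label(label: str) -> Counter:
    """Parse a fragment label such as ``[M+H-2Glc-Ara-C8H16O2-2H2O]+`` (or
    the bare ``M+H-...`` form) into a loss multiset Counter."""
    text = label.strip().removeprefix("[").removesuffix("+").removesuffix("]")
    parts = text.split("-")
    if parts[0] not in ("M+H", "M + H"):
        raise ValueError(f"unsupported fragment label {label!r}")
    losses: Counter = Counter()
    for tok in parts[1:]:
        tok = tok.strip()
        count = 1
        # a leading multiplier, but not the digits of a chemical formula
        i = 0
        while i < len(tok) and tok[i].isdigit():
            i += 1
        if i and tok[i:] in _LOSS_ALIASES:
            count, tok = int(tok[:i]), tok[i:]
        if tok not in _LOSS_ALIASES:
            raise ValueError(f"unknown loss token {tok!r} in {label!r}")
        losses[_LOSS_ALIASES[tok]] += count
    return losses


def _format_label(losses: Counter, charge_suffix: str = "+") -> str:
    order = ["Glc", "Ara", "EF144", "EF142", "EF160", "H2O"]
    toks = []
    for key in order:
        n = losses.get(key, 0)
        if not n:
            continue
        name = {"EF144": "C8H16O2", "EF142": "C8H14O2", "EF160": "C8H16O3"}.get(key, key)
        toks.append(name if n == 1 else f"{n}{name}")
    body = "-".join(["M+H"] + toks)
    return f"[{body}]{charge_suffix}"


@dataclass(frozen=True)
class LadderIon:
    """A theoretical fragment of the cohesive loss ladder."""

    label: str
    losses: Tuple[Tuple[str, int], ...]  # sorted (loss, count) pairs
    mz: float

    @property
    def loss_counter(self) -> Counter:
        return Counter(dict(self.losses))


def generate_ladder(candidate: Candidate, species: str = "[M+H]+") -> List[LadderIon]:
    """All ladder ions of a candidate: every sugar subset, optionally the
    backbone's E/F-ring loss, then 0..max sequential waters, deduplicated
    by theoretical m/z (1e-4)."""
    base = adduct_mz(candidate.theoretical_mass, species)
    agl = candidate.aglycone
    ions: List[LadderIon] = []
    seen_mz: List[float] = []
    for n_glc in range(candidate.glycan.n_glc + 1):
        for n_ara in range(candidate.glycan.n_ara + 1):
            for ef in (0, 1):
                for n_w in range(agl.max_water_losses + 1):
                    losses = Counter()
                    if n_glc:
                        losses["Glc"] = n_glc
                    if n_ara:
                        losses["Ara"] = n_ara
                    if ef:
                        losses[agl.ef_loss] = 1
                    if n_w:
                        losses["H2O"] = n_w
                    mz = base - sum(neutral_loss_mass(k) * n for k, n in losses.items())
                    if mz <= 0:
                        continue
                    if any(abs(mz - m) <= 1e-4 for m in seen_mz):
                        continue
                    seen_mz.append(mz)
                    ions.append(LadderIon(
                        label=_format_label(losses),
                        losses=tuple(sorted(losses.items())),
                        mz=mz,
                    ))
    ions.sort(key=lambda i: -i.mz)
    return ions


@dataclass(frozen=True)
class FragmentMatch:
    peak: Peak
    ion: LadderIon
    delta_mz: float  # theoretical - observed
    ppm: float


def match_ladder(spectrum: Spectrum, ladder: Sequence[LadderIon],
                 frag_tol_da: float = 0.02) -> List[FragmentMatch]:
    """Greedy nearest-first one-to-one assignment of peaks to ladder ions
    within an absolute fragment tolerance (Da)."""
    pairs = []
    for pi, peak in enumerate(spectrum.peaks):
        for li, ion in enumerate(ladder):
            d = ion.mz - peak.mz
            if abs(d) <= frag_tol_da:
                pairs.append((abs(d), pi, li, d))
    pairs.sort()
    used_p, used_l = set(), set()
    matches: List[FragmentMatch] = []
    for _, pi, li, d in pairs:
        if pi in used_p or li in used_l:
            continue
        used_p.add(pi)
        used_l.add(li)
        ion = ladder[li]
        matches.append(FragmentMatch(spectrum.peaks[pi], ion, d, ppm_error(ion.mz, spectrum.peaks[pi].mz)))
    matches.sort(key=lambda m: -m.peak.mz)
    return matches


# ---------------------------------------------------------------------------
# skeleton classification + full annotation
# ---------------------------------------------------------------------------

_INTACT_POSITIVE = ("[M+H]+", "[M+Na]+", "[M+NH4]+")


def classify_skeleton(candidate: Candidate, precursor_mz: float,
                      frag_tol_da: float = 0.02) -> Tuple[str, bool]:
    """Skeleton class implied by the decomposition, with a consistency flag
    against the observed positive-mode precursor.

    A furostane (decomposition required the extra water) should be seen as
    [M+H-H2O]+; an (iso)spirostane as an intact cation.  The flag is False
    when the precursor contradicts that expectation; callers surface such
    annotations as "ambiguous" rather than silently resolving them.
    """
    skeleton = candidate.skeleton
    if skeleton == FUROSTANE:
        expected = [adduct_mz(candidate.theoretical_mass, "[M+H-H2O]+")]
    else:
        expected = [adduct_mz(candidate.theoretical_mass, s) for s in _INTACT_POSITIVE]
    consistent = any(abs(precursor_mz - e) <= frag_tol_da for e in expected)
    return skeleton, consistent


@dataclass
class AnnotationConfig:
    """Tunable parameters of the annotation pipeline.

    Defaults are the standard high-resolution settings: 5 ppm precursor
    accuracy, 0.02 Da fragment tolerance, at least 3 matched fragments.
    """

    tol_ppm: float = 5.0
    frag_tol_da: float = 0.02
    min_matched: int = 3
    max_glc: int = 4
    max_ara: int = 2
    allow_extra_water: bool = True
    aglycones: Optional[List[AglyconeDef]] = None

    def library(self) -> List[AglyconeDef]:
        return self.aglycones if self.aglycones is not None else default_aglycones()

    @classmethod
    def from_file(cls, path) -> "AnnotationConfig":
        """Read a simple ``key = value`` config file; unknown keys error."""
        cfg = cls()
        text = path.read_text() if hasattr(path, "read_text") else open(path).read()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value, got {line!r}")
            key, value = (t.strip() for t in line.split("=", 1))
            if key in ("tol_ppm", "frag_tol_da"):
                setattr(cfg, key, float(value))
            elif key in ("min_matched", "max_glc", "max_ara"):
                setattr(cfg, key, int(value))
            elif key == "allow_extra_water":
                cfg.allow_extra_water = value.lower() in ("1", "true", "yes")
            elif key == "aglycone_library":
                cfg.aglycones = load_aglycone_library(value)
            else:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
        return cfg


@dataclass
class Annotation:
    """An accepted structural annotation of one spectrum."""

    spectrum_id: str
    aglycone: str
    glycan: GlycanComposition
    skeleton: str
    neutral_mass: float
    species: str
    ppm: float
    matched_fragments: List[FragmentMatch]
    score: float
    support: int
    consistent: bool
    sample_part: Optional[str] = None

    @property
    def n_matched(self) -> int:
        return len(self.matched_fragments)


def _corroborate(candidate: Candidate, ions: Sequence[Tuple[str, float]],
                 tol_da: float) -> List[Tuple[int, str, float]]:
    """Observed ions explained by the candidate's theoretical mass:
    (ion index, species, implied neutral mass), at most one species per
    ion (the closest)."""
    out: List[Tuple[int, str, float]] = []
    for idx, (polarity, mz) in enumerate(ions):
        hit = None
        for name, spec in ADDUCTS.items():
            if spec.polarity != polarity:
                continue
            d = abs(mz - spec.mz(candidate.theoretical_mass))
            if d <= tol_da and (hit is None or d < hit[0]):
                hit = (d, name, spec.neutral_mass(mz))
        if hit is not None:
            out.append((idx, hit[1], hit[2]))
    return out


def annotate(spectrum: Spectrum, config: Optional[AnnotationConfig] = None) -> List[Annotation]:
    """Full dereplication of one positive-mode spectrum.

    Pipeline: infer neutral-mass hypotheses from all precursor-level ion
    observations, decompose them over the backbone/sugar grid (with a 2x
    candidate-generation margin so a single noisy ion cannot mask the
    true composition), refine each candidate's mass as the median over
    the ion species that corroborate it, gate at the precursor tolerance,
    predict the candidate's ladder, match it to the peaks, and classify
    the skeleton.  Ranking keys, in order: matched fragment count; number
    of corroborating ion species; skeleton/ion-species consistency;
    |precursor ppm|.  Candidates matching fewer than ``min_matched``
    fragments are rejected; an empty list means unannotated.
    """
    config = config or AnnotationConfig()
    if spectrum.polarity != "positive":
        return []
    ions = spectrum.all_ions()
    candidates: Dict[Tuple[str, int, int, int], Candidate] = {}
    for mc in infer_neutral_mass(ions, config.tol_ppm):
        for cand in decompose_mass(mc.mass, 2.0 * config.tol_ppm,
                                   aglycones=config.library(),
                                   max_glc=config.max_glc, max_ara=config.max_ara,
                                   allow_extra_water=config.allow_extra_water):
            key = (cand.aglycone.name, cand.glycan.n_glc, cand.glycan.n_ara, cand.extra_water)
            candidates.setdefault(key, cand)
    results: List[Annotation] = []
    for cand in candidates.values():
        support = _corroborate(cand, ions, config.frag_tol_da)
        if not support:
            continue
        consensus = statistics.median(m for _, _, m in support)
        ppm = ppm_error(cand.theoretical_mass, consensus)
        if abs(ppm) > config.tol_ppm:
            continue
        ladder = generate_ladder(cand)
        matches = match_ladder(spectrum, ladder, config.frag_tol_da)
        if len(matches) < config.min_matched:
            continue
        skeleton, consistent = classify_skeleton(cand, spectrum.precursor_mz,
                                                 config.frag_tol_da)
        species = next((name for idx, name, _ in support if idx == 0), "")
        results.append(Annotation(
            spectrum_id=spectrum.id,
            aglycone=cand.aglycone.name,
            glycan=cand.glycan,
            skeleton=skeleton if consistent else AMBIGUOUS,
            neutral_mass=consensus,
            species=species,
            ppm=ppm,
            matched_fragments=matches,
            score=len(matches) - abs(ppm) / 10.0,
            support=len(support),
            consistent=consistent,
            sample_part=spectrum.sample_part,
        ))
    results.sort(key=_rank_key)
    return results


def _rank_key(a: Annotation):
    return (-a.n_matched, -a.support, not a.consistent, abs(a.ppm), a.aglycone)
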
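"""Seeded generator of ground-truth saponin structures and in-silico spectra.

The generator samples structures from the same space the annotator
searches — six sapogenin backbones, 0–4 glucosyl and 0–2 arabinosyl
residues, furostane or (iso)spirostane behaviour — and emits positive-mode
MS/MS spectra with the cohesive loss-ladder structure of high-energy CID
saponin spectra:

* glycosidic ions (partial sugar losses) are minor peaks,
* the spectrum is dominated by the sapogenin core series (full sugar
  loss, then sequential waters and the E/F-ring retro-cleavage) with a
  geometric intensity decay per further loss step,
* each backbone class additionally yields skeleton-specific low-mass
  ring-cleavage ions (prominent at 50 eV and not homologous across
  classes, unlike the loss ladder, which shifts rigidly with the
  backbone mass),
* furostanes are emitted as [M+H-H2O]+ with the labile water lost on
  every fragment,
* every m/z carries multiplicative Gaussian ppm noise and Poisson decoy
  peaks are added uniformly below the precursor,
* negative-mode precursor observations ([M-H]-, [M+HCOO]-) accompany
  each spectrum, as they would from the survey scans.

Intensities are relative (no table of real intensities exists to
calibrate against); the defaults are stated in the package docs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .decompose import Candidate, GlycanComposition, default_aglycones
from .masses import adduct_mz, neutral_loss_mass
from .spectra import Peak, Spectrum, write_mgf

__all__ = ["GeneratorConfig", "GroundTruth", "generate_dataset",
           "primary_spectra", "export_fixture_mgf", "three_family_dataset"]

_W = neutral_loss_mass("H2O")
PARTS = ("leaf", "stem", "root")

#: class-specific ring-cleavage ions: offsets (Da) below the sapogenin
#: [M+H]+ ion.  The offsets differ between classes (high-energy cleavage
#: chemistry depends on the C-5/C-6/C-27 functionalization), so unlike the
#: loss ladder these ions neither direct- nor shift-match across classes.
_CLASS_SIGNATURE_OFFSETS: Dict[str, Tuple[float, ...]] = {
    "diosgenin": (119.317, 146.658, 173.999, 201.340),
    "laxogenin": (125.234, 152.575, 179.916, 207.257),
    "sarsa/tigogenin": (131.151, 158.492, 185.833, 213.174),
    "27OH-sarsa/tigogenin": (137.068, 164.409, 191.750, 219.091),
    "sieboldigenin": (142.985, 170.326, 197.667, 225.008),
    "3,6,27-triOH-furostane": (148.902, 176.243, 203.584, 230.925),
}

#: relative intensities of the signature ions (low-mass ions dominate
#: high-energy CID steroid spectra)
_SIGNATURE_PATTERN = (1.2, 0.9, 0.7, 0.5)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic saponin universe.

    ``decoy_rate`` is the expected number of decoy peaks per spectrum
    (Poisson); with the default ladder sizes, a rate of 3 makes decoys
    roughly 20% of the peaks.  ``ppm_sigma`` is the s.d. of the relative
    mass error in ppm, matching low-ppm QToF accuracy.
    """

    seed: int = 0
    n_compounds: int = 50
    aglycone_weights: Optional[Dict[str, float]] = None  # None = uniform
    p_furostane: float = 0.5
    glc_range: Tuple[int, int] = (0, 4)
    ara_range: Tuple[int, int] = (0, 2)
    ppm_sigma: float = 3.0
    decoy_rate: float = 3.0
    intensity_decay: float = 0.7
    glycoside_intensity: float = 0.15
    signature_intensity: float = 1.0  # scale of the class ring-cleavage ions
    parts_profile: Dict[str, float] = field(
        default_factory=lambda: {"leaf": 0.85, "stem": 0.9, "root": 0.95})
    rt_range: Tuple[float, float] = (5.0, 35.0)

    def validate(self) -> None:
        if not 0 <= self.p_furostane <= 1:
            raise ValueError("p_furostane must be a probability")
        for part, p in self.parts_profile.items():
            if part not in PARTS or not 0 <= p <= 1:
                raise ValueError(f"bad parts_profile entry {part!r}: {p}")
        if self.glc_range[0] < 0 or self.ara_range[0] < 0:
            raise ValueError("sugar ranges must be non-negative")
        if self.ppm_sigma < 0 or self.decoy_rate < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0 < self.intensity_decay <= 1:
            raise ValueError("intensity_decay must be in (0, 1]")
        if self.aglycone_weights is not None:
            names = {a.name for a in default_aglycones()}
            unknown = set(self.aglycone_weights) - names
            if unknown:
                raise ValueError(f"unknown aglycone classes in weights: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    compound_id: str
    aglycone: str
    n_glc: int
    n_ara: int
    skeleton: str  # furostane | (iso)spirostane
    parts: Tuple[str, ...]
    neutral_mass: float
    rt: float


def _emitted_ions(candidate: Candidate, decay: float,
                  glyco_intensity: float) -> List[Tuple[Counter, float]]:
    """(loss multiset, relative intensity) of the chemically prominent ions."""
    n_glc, n_ara = candidate.glycan.n_glc, candidate.glycan.n_ara
    w0 = candidate.extra_water  # furostane labile water, lost on every ion
    ions: List[Tuple[Counter, float]] = []
    # glycosidic series: partial sugar losses, minor
    for i in range(n_glc + 1):
        for j in range(n_ara + 1):
            if i == n_glc and j == n_ara:
                continue
            losses = Counter({"Glc": i, "Ara": j, "H2O": w0})
            ions.append((+losses, glyco_intensity))
    # sapogenin core series: all sugars gone, then waters, then E/F cleavage
    base = Counter({"Glc": n_glc, "Ara": n_ara, "H2O": w0})
    for k in range(4):
        losses = base.copy()
        losses["H2O"] += k
        ions.append((+losses, decay ** k))
    for k in range(3):
        losses = base.copy()
        losses[candidate.aglycone.ef_loss] += 1
        losses["H2O"] += k
        ions.append((+losses, decay ** (k + 1)))
    return ions


def _spectrum_for(truth: GroundTruth, candidate: Candidate, part: Optional[str],
                  config: GeneratorConfig, rng: np.random.Generator) -> Spectrum:
    base_mz = adduct_mz(candidate.theoretical_mass, "[M+H]+")
    noise = lambda: 1.0 + rng.normal(0.0, config.ppm_sigma * 1e-6)
    emitted = _emitted_ions(candidate, config.intensity_decay, config.glycoside_intensity)
    peaks: List[Peak] = []
    true_pairs: List[Tuple[float, float, str]] = []
    precursor_obs = None
    precursor_losses = Counter({"H2O": candidate.extra_water})
    for losses, intensity in emitted:
        theo = base_mz - sum(neutral_loss_mass(k) * n for k, n in losses.items())
        obs = theo * noise()
        peaks.append(Peak(obs, intensity))
        true_pairs.append((theo, obs, "ladder"))
        if losses == precursor_losses:
            precursor_obs = obs
    assert precursor_obs is not None
    sapogenin_mh = adduct_mz(candidate.aglycone.mass, "[M+H]+")
    offsets = _CLASS_SIGNATURE_OFFSETS.get(candidate.aglycone.name, ())
    for offset, rel in zip(offsets, _SIGNATURE_PATTERN):
        theo = sapogenin_mh - offset
        obs = theo * noise()
        peaks.append(Peak(obs, rel * config.signature_intensity))
        true_pairs.append((theo, obs, "signature"))
    n_decoys = int(rng.poisson(config.decoy_rate))
    for _ in range(n_decoys):
        peaks.append(Peak(float(rng.uniform(100.0, precursor_obs)),
                          float(rng.uniform(0.02, 0.3))))
    neg_ions = [
        ("negative", adduct_mz(candidate.theoretical_mass, "[M-H]-") * noise()),
        ("negative", adduct_mz(candidate.theoretical_mass, "[M+HCOO]-") * noise()),
    ]
    species = "[M+H-H2O]+" if candidate.extra_water else "[M+H]+"
    sid = truth.compound_id if part is None else f"{truth.compound_id}_{part}"
    return Spectrum(
        id=sid,
        precursor_mz=precursor_obs,
        polarity="positive",
        rt=truth.rt,
        peaks=peaks,
        precursor_species=species,
        sample_part=part,
        ions=neg_ions,
        metadata={
            "compound_id": truth.compound_id,
            "true_peaks": true_pairs,
            "n_decoys": n_decoys,
        },
    )


def generate_dataset(config: GeneratorConfig
                     ) -> Tuple[List[GroundTruth], Dict[str, List[Spectrum]]]:
    """Sample ``n_compounds`` structures and emit per-part spectra.

    Deterministic for a fixed config (same seed => identical output).
    Each compound is present in each part with the configured
    probability (at least one part is guaranteed, defaulting to root),
    and every part occurrence gets an independently noised spectrum.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    library = {a.name: a for a in default_aglycones()}
    names = sorted(library)
    if config.aglycone_weights:
        weights = np.array([config.aglycone_weights.get(n, 0.0) for n in names], float)
    else:
        weights = np.ones(len(names))
    weights = weights / weights.sum()

    truths: List[GroundTruth] = []
    by_part: Dict[str, List[Spectrum]] = {p: [] for p in config.parts_profile}
    for i in range(config.n_compounds):
        name = names[int(rng.choice(len(names), p=weights))]
        agl = library[name]
        n_glc = int(rng.integers(config.glc_range[0], config.glc_range[1] + 1))
        n_ara = int(rng.integers(config.ara_range[0], config.ara_range[1] + 1))
        furostane = bool(rng.random() < config.p_furostane)
        parts = tuple(p for p in config.parts_profile
                      if rng.random() < config.parts_profile[p])
        if not parts:
            parts = ("root",) if "root" in config.parts_profile else tuple(config.parts_profile)[:1]
        glycan = GlycanComposition(n_glc, n_ara)
        mass = agl.mass + glycan.residue_mass + (int(furostane)) * _W
        truth = GroundTruth(
            compound_id=f"c{i:04d}", aglycone=name, n_glc=n_glc, n_ara=n_ara,
            skeleton="furostane" if furostane else "(iso)spirostane",
            parts=parts, neutral_mass=mass,
            rt=float(rng.uniform(*config.rt_range)),
        )
        truths.append(truth)
        candidate = Candidate(agl, glycan, int(furostane), mass, 0.0)
        for part in parts:
            by_part[part].append(_spectrum_for(truth, candidate, part, config, rng))
    return truths, by_part


def primary_spectra(truths: Sequence[GroundTruth],
                    by_part: Dict[str, List[Spectrum]]) -> List[Spectrum]:
    """One spectrum per compound (its first part), for recovery studies."""
    index = {}
    for part, spectra in by_part.items():
        for s in spectra:
            index[s.id] = s
    out = []
    for t in truths:
        out.append(index[f"{t.compound_id}_{t.parts[0]}"])
    return out


def export_fixture_mgf(truths: Sequence[GroundTruth],
                       by_part: Dict[str, List[Spectrum]],
                       outdir) -> Dict[str, str]:
    """Write one MGF per part plus a ground-truth TSV; returns the paths."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for part, spectra in by_part.items():
        if not spectra:
            continue
        path = os.path.join(str(outdir), f"{part}.mgf")
        write_mgf(spectra, path)
        paths[part] = path
    gt_path = os.path.join(str(outdir), "ground_truth.tsv")
    with open(gt_path, "w") as fh:
        fh.write("compound_id\taglycone\tn_glc\tn_ara\tskeleton\tneutral_mass\trt\tparts\n")
        for t in truths:
            fh.write(f"{t.compound_id}\t{t.aglycone}\t{t.n_glc}\t{t.n_ara}\t"
                     f"{t.skeleton}\t{t.neutral_mass:.4f}\t{t.rt:.2f}\t{','.join(t.parts)}\n")
    paths["ground_truth"] = gt_path
    return paths


#: disjoint glycoform sets per family for the three-family network study.
#: Identical sugar compositions on different cores produce fully
#: shift-aligned ladders (near-cosine-1 analog links), so family
#: separability requires distinct glycoforms; each family also contributes
#: its free sapogenin as the seed node.
_FAMILY_GLYCOFORMS: Dict[str, List[Tuple[int, int]]] = {
    "laxogenin": [(1, 0), (2, 1), (3, 1), (4, 1)],
    "diosgenin": [(1, 1), (2, 2), (3, 0), (4, 0)],
    "sarsa/tigogenin": [(0, 1), (1, 2), (2, 0), (3, 2)],
}


def three_family_dataset(seed: int = 0
                         ) -> Tuple[List[GroundTruth], List[Spectrum], Dict[str, str]]:
    """A deterministic three-family glycoside dataset for networking.

    Returns (ground truths, spectra, family -> seed spectrum id); the
    seeds are the free sapogenin spectra of each family.  Low mass noise,
    no decoys.
    """
    config = GeneratorConfig(seed=seed, ppm_sigma=1.0, decoy_rate=0.0)
    rng = np.random.default_rng(seed)
    library = {a.name: a for a in default_aglycones()}
    truths: List[GroundTruth] = []
    spectra: List[Spectrum] = []
    seed_ids: Dict[str, str] = {}
    i = 0
    for family, comps in _FAMILY_GLYCOFORMS.items():
        agl = library[family]
        for n_glc, n_ara in [(0, 0)] + comps:
            glycan = GlycanComposition(n_glc, n_ara)
            mass = agl.mass + glycan.residue_mass
            truth = GroundTruth(
                compound_id=f"f{i:03d}", aglycone=family, n_glc=n_glc, n_ara=n_ara,
                skeleton="(iso)spirostane", parts=("root",), neutral_mass=mass,
                rt=float(rng.uniform(*config.rt_range)),
            )
            candidate = Candidate(agl, glycan, 0, mass, 0.0)
            spec = _spectrum_for(truth, candidate, None, config, rng)
            truths.append(truth)
            spectra.append(spec)
            if (n_glc, n_ara) == (0, 0):
                seed_ids[family] = spec.id
            i += 1
    return truths, spectra, seed_ids
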
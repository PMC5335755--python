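"""Synthetic multi-species MS/MS datasets with technical replicates.

The generator emulates the structure of a shotgun-proteomics benchmark:
each species owns a library of template spectra (its "peptides"); a
technical replicate of a species is produced by re-measuring that library
with data-dependent-acquisition-style stochasticity -- whole-spectrum
dropout (DDA picks different precursors in each replicate), small m/z
jitter on fragment peaks and on the precursor, multiplicative lognormal
intensity noise, per-peak dropout and local reordering of elution order.
A fraction of the templates can be shared across species to emulate
conserved peptides. Each surviving spectrum is annotated with its
template identifier, standing in for a peptide-spectrum match, with a
configurable fraction left unannotated.

Generation is fully deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np

from .modes import AnnotationTable
from .spectra import Run, Spectrum

__all__ = [
    "SyntheticConfig",
    "TemplateSpectrum",
    "SpeciesLibrary",
    "generate_species_library",
    "generate_run",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for synthetic data generation.

    Defaults describe a desk-scale benchmark: 3 species measured in
    triplicate, 120 spectra per run, ~30% replicate-to-replicate spectrum
    dropout (DDA variability), fragment m/z jitter far below the 0.2 Th
    bin width, precursor jitter far below the 10 ppm matching tolerance,
    and 40% of spectra left without annotation.
    """

    n_species: int = 3
    replicates_per_species: int = 3
    spectra_per_run: int = 120
    peaks_per_spectrum: Tuple[int, int] = (20, 60)
    mz_range: Tuple[float, float] = (100.0, 1500.0)
    precursor_range: Tuple[float, float] = (300.0, 1500.0)
    charge_weights: Tuple[Tuple[int, float], ...] = ((2, 0.6), (3, 0.4))
    mz_jitter_sd: float = 0.002          # Th, fragment peaks
    precursor_jitter_ppm: float = 2.0    # sd of the precursor ppm error
    intensity_noise_cv: float = 0.25
    peak_dropout_rate: float = 0.05
    spectrum_dropout_rate: float = 0.25
    shared_library_fraction: float = 0.0
    retention_shuffle_window: int = 10
    annotation_missing_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("peak_dropout_rate", "spectrum_dropout_rate",
                     "annotation_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0.0 <= self.shared_library_fraction <= 1.0:
            raise ValueError("shared_library_fraction must be in [0, 1]")
        if self.n_species < 1 or self.replicates_per_species < 1:
            raise ValueError("need at least one species and one replicate")


@dataclass(frozen=True)
class TemplateSpectrum:
    """A noiseless library spectrum; ``template_id`` doubles as the
    ground-truth peptide identifier."""

    template_id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    charge: int


@dataclass(frozen=True)
class SpeciesLibrary:
    species_index: int
    templates: Tuple[TemplateSpectrum, ...]


def _rng(config: SyntheticConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2 ** 31), *stream])


def _random_template(rng: np.random.Generator, config: SyntheticConfig,
                     template_id: str) -> TemplateSpectrum:
    lo, hi = config.peaks_per_spectrum
    n_peaks = int(rng.integers(lo, hi + 1))
    mz = np.sort(rng.uniform(*config.mz_range, size=n_peaks))
    intensity = rng.lognormal(mean=math.log(1000.0), sigma=1.0, size=n_peaks)
    charges = [c for c, _ in config.charge_weights]
    weights = np.array([w for _, w in config.charge_weights], dtype=float)
    charge = int(rng.choice(charges, p=weights / weights.sum()))
    precursor = float(rng.uniform(*config.precursor_range))
    return TemplateSpectrum(template_id, mz, intensity, precursor, charge)


def _shared_pool(config: SyntheticConfig) -> List[TemplateSpectrum]:
    n_shared = round(config.shared_library_fraction * config.spectra_per_run)
    rng = _rng(config, 7)
    return [_random_template(rng, config, f"shared_t{i:05d}")
            for i in range(n_shared)]


def generate_species_library(config: SyntheticConfig,
                             species_index: int) -> SpeciesLibrary:
    """Template library of one species: a shared cross-species pool plus
    species-specific templates, ``spectra_per_run`` in total."""
    shared = _shared_pool(config)
    rng = _rng(config, 100, species_index)
    specific = [
        _random_template(rng, config, f"sp{species_index}_t{i:05d}")
        for i in range(config.spectra_per_run - len(shared))
    ]
    return SpeciesLibrary(species_index, tuple(shared + specific))


def _measure(library: SpeciesLibrary, config: SyntheticConfig,
             replicate_index: int) -> Tuple[Run, List[TemplateSpectrum]]:
    """Re-measure a library with noise; track template identity per scan."""
    rng = _rng(config, 1000, library.species_index, replicate_index)
    sigma = math.sqrt(math.log1p(config.intensity_noise_cv ** 2))
    surviving: List[Tuple[Spectrum, TemplateSpectrum]] = []
    for tmpl in library.templates:
        if rng.random() < config.spectrum_dropout_rate:
            continue
        mz = tmpl.mz + rng.normal(0.0, config.mz_jitter_sd, size=tmpl.mz.size)
        noise = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                              size=tmpl.intensity.size)
        intensity = tmpl.intensity * noise
        keep = rng.random(tmpl.mz.size) >= config.peak_dropout_rate
        ppm_err = rng.normal(0.0, config.precursor_jitter_ppm)
        precursor = tmpl.precursor_mz * (1.0 + ppm_err * 1e-6)
        order = np.argsort(mz[keep], kind="stable")
        surviving.append((Spectrum(
            scan_number=1,  # reassigned below
            precursor_mz=precursor,
            precursor_charge=tmpl.charge,
            mz=mz[keep][order],
            intensity=intensity[keep][order],
        ), tmpl))
    # local elution reordering: shuffle within consecutive windows
    w = max(1, config.retention_shuffle_window)
    reordered: List[Tuple[Spectrum, TemplateSpectrum]] = []
    for start in range(0, len(surviving), w):
        block = surviving[start:start + w]
        reordered.extend(block[i] for i in rng.permutation(len(block)))
    spectra = [replace(s, scan_number=i + 1, retention_time=float(i + 1))
               for i, (s, _) in enumerate(reordered)]
    run = Run(run_id=f"S{library.species_index}_R{replicate_index}",
              spectra=spectra)
    return run, [tmpl for _, tmpl in reordered]


def generate_run(library: SpeciesLibrary, config: SyntheticConfig,
                 replicate_index: int) -> Run:
    """One technical replicate: the library re-measured with noise."""
    return _measure(library, config, replicate_index)[0]


def generate_dataset(config: SyntheticConfig
                     ) -> Tuple[List[Run], List[str], AnnotationTable]:
    """All runs of the study plus group labels and the annotation table.

    Returns ``n_species * replicates_per_species`` runs, one species label
    per run, and an annotation table mapping each surviving spectrum to
    its template identifier (a fraction ``annotation_missing_rate`` of
    spectra is left unannotated).
    """
    runs: List[Run] = []
    labels: List[str] = []
    ann = AnnotationTable()
    for sp in range(config.n_species):
        library = generate_species_library(config, sp)
        for rep in range(config.replicates_per_species):
            run, templates = _measure(library, config, rep)
            ann_rng = _rng(config, 2000, sp, rep)
            for spectrum, tmpl in zip(run, templates):
                if ann_rng.random() >= config.annotation_missing_rate:
                    ann.add(run.run_id, spectrum.scan_number, tmpl.template_id)
            runs.append(run)
            labels.append(f"S{sp}")
    return runs, labels, ann


def write_dataset(runs: Sequence[Run], labels: Sequence[str],
                  ann: AnnotationTable, outdir: Union[str, Path]) -> None:
    """Write runs as MGF plus groups.tsv and psms.tsv."""
    from .io import write_mgf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for run in runs:
        write_mgf(run, outdir / f"{run.run_id}.mgf")
    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("run_id\tgroup\n")
        for run, lab in zip(runs, labels):
            fh.write(f"{run.run_id}\t{lab}\n")
    ann.to_tsv(outdir / "psms.tsv")
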
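"""Transcript construction and RNA hybridisation/folding energetics.

Internal Shine-Dalgarno-like motifs created by a synonymous substitution
can stall elongating ribosomes by pairing with the 16S rRNA anti-SD tail
(consensus 5'CACCUCCU3').  This module scans mutant transcripts with a
10-nt sliding window, scoring each window's bimolecular duplex energy with
the anti-SD, and summarises the mutant-minus-WT difference over the windows
a codon change can affect (delta-aSD; positive = less predicted pausing
than WT).  It also profiles transcript stability as the mean of 30-nt
sliding-window minimum free energies (delta-MFE; positive = destabilised
mutant mRNA) and predicts ribosome-binding-site occlusion as the unpaired
fraction of the SD span in the MFE structure of the initiation region.

The transcript model is the putative SD stretch starting 18 nt upstream of
the start codon followed by the full coding sequence (324 nt for the
306-nt ccdB CDS).

Thermodynamics are delegated to a pluggable folding engine; the default is
the ViennaRNA nearest-neighbor implementation at 37 degrees C.  Duplex
energies use a bimolecular model with intramolecular pairing disallowed;
single-strand MFEs use the full intramolecular model.  Predicted
interaction energies >= 0 ("no stable duplex") are recorded as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_counts import MutantVariant

ANTI_SD = "CACCUCCU"
DEFAULT_UPSTREAM = 18


class EngineError(RuntimeError):
    """Folding-engine failure, wrapped with calling context."""


def to_rna(sequence: str) -> str:
    return str(sequence).upper().replace("T", "U")


_RNA_COMPLEMENT = str.maketrans("AUGC", "UACG")


def rna_reverse_complement(sequence: str) -> str:
    return to_rna(sequence).translate(_RNA_COMPLEMENT)[::-1]


@dataclass
class ViennaEngine:
    """ViennaRNA-backed folding engine (Turner parameters, deterministic).

    temperature is in degrees C.  The engine exposes three primitives:
    duplex_energy (bimolecular, no intramolecular pairing), mfe and
    mfe_structure (intramolecular).
    """

    temperature: float = 37.0

    @property
    def parameter_set(self) -> str:
        import RNA

        return f"ViennaRNA {RNA.__version__} default Turner parameters"

    def _md(self):
        import RNA

        md = RNA.md()
        md.temperature = self.temperature
        return md

    def duplex_energy(self, seq_a: str, seq_b: str) -> float:
        """Minimum bimolecular interaction free energy (kcal/mol, <= 0)."""
        import RNA

        a, b = to_rna(seq_a), to_rna(seq_b)
        if not a or not b:
            raise EngineError("empty sequence passed to duplex_energy")
        try:
            if self.temperature != 37.0:
                old = RNA.cvar.temperature
                RNA.cvar.temperature = self.temperature
                try:
                    duplex = RNA.duplexfold(a, b)
                finally:
                    RNA.cvar.temperature = old
            else:
                duplex = RNA.duplexfold(a, b)
        except Exception as exc:  # pragma: no cover - engine internal failure
            raise EngineError(f"duplexfold failed for {a}/{b}: {exc}") from exc
        return min(0.0, float(duplex.energy))

    def mfe(self, sequence: str) -> float:
        """Single-strand minimum free energy (kcal/mol, <= 0)."""
        return self._fold(sequence)[1]

    def mfe_structure(self, sequence: str) -> str:
        """Dot-bracket MFE structure of a single strand."""
        return self._fold(sequence)[0]

    def _fold(self, sequence: str) -> tuple[str, float]:
        import RNA

        seq = to_rna(sequence)
        if not seq:
            raise EngineError("empty sequence passed to fold")
        try:
            fc = RNA.fold_compound(seq, self._md())
            structure, energy = fc.mfe()
        except Exception as exc:  # pragma: no cover
            raise EngineError(f"fold failed for {seq}: {exc}") from exc
        return structure, min(0.0, float(energy))


@dataclass
class TranscriptModel:
    """An mRNA with SD-region offset and coding coordinates (1-based)."""

    sequence: str
    cds_start: int
    cds_length: int
    sd_offset: int = 1

    def __post_init__(self) -> None:
        self.sequence = to_rna(self.sequence)
        if self.cds_length % 3:
            raise ValueError("cds_length must be divisible by 3")
        if self.cds_start + self.cds_length - 1 > len(self.sequence):
            raise ValueError("coding region extends beyond transcript")

    def codon_span(self, position: int) -> tuple[int, int]:
        """1-based inclusive nucleotide span of a codon within the transcript."""
        if not 1 <= position <= self.cds_length // 3:
            raise ValueError(f"codon position {position} outside CDS")
        start = self.cds_start + 3 * (position - 1)
        return start, start + 2


@dataclass
class EnergyProfile:
    """Ordered sliding-window energies (kcal/mol, <= 0)."""

    window_size: int
    step: int
    energies: list[float]

    def __len__(self) -> int:
        return len(self.energies)


def window_count(length: int, window: int, step: int = 1) -> int:
    if length < window:
        raise ValueError(f"sequence length {length} shorter than window {window}")
    return (length - window) // step + 1


def build_transcript(
    operon_sequence: str,
    variant: MutantVariant | None = None,
    cds_offset: int = 1,
    cds_length: int | None = None,
    upstream: int = DEFAULT_UPSTREAM,
) -> TranscriptModel:
    """Extract the SD + CDS transcript and apply one codon substitution.

    ``cds_offset`` is the 1-based position of the first CDS base (the A of
    AUG) within ``operon_sequence``; the transcript keeps ``upstream``
    bases before it.  ``variant=None`` (or an identity variant) returns the
    wild-type transcript.
    """
    seq = to_rna(operon_sequence)
    if cds_length is None:
        cds_length = len(seq) - cds_offset + 1
    if cds_length % 3:
        raise ValueError("cds_length must be divisible by 3")
    if cds_offset - 1 < upstream:
        raise ValueError(
            f"operon provides only {cds_offset - 1} nt upstream of the CDS, "
            f"{upstream} required"
        )
    start = cds_offset - upstream
    transcript = seq[start - 1 : cds_offset + cds_length - 1]
    model = TranscriptModel(
        sequence=transcript, cds_start=upstream + 1, cds_length=cds_length
    )
    if variant is None or variant.is_identity:
        return model
    lo, hi = model.codon_span(variant.position)
    current = model.sequence[lo - 1 : hi].replace("U", "T")
    if current != variant.wt_codon:
        raise ValueError(
            f"transcript codon {current} at position {variant.position} does "
            f"not match variant WT codon {variant.wt_codon}"
        )
    mutated = (
        model.sequence[: lo - 1] + to_rna(variant.mut_codon) + model.sequence[hi:]
    )
    return TranscriptModel(
        sequence=mutated, cds_start=model.cds_start, cds_length=cds_length
    )


def sd_duplex_energy(
    sd_sequence: str,
    asd_sequence: str = ANTI_SD,
    engine: ViennaEngine | None = None,
) -> float:
    """Minimum SD:anti-SD bimolecular interaction energy (kcal/mol)."""
    engine = engine or ViennaEngine()
    return engine.duplex_energy(sd_sequence, asd_sequence)


def asd_window_profile(
    transcript: TranscriptModel | str,
    engine: ViennaEngine | None = None,
    window: int = 10,
    step: int = 1,
    asd_sequence: str = ANTI_SD,
) -> EnergyProfile:
    """Anti-SD duplex energy of every sliding window along the transcript."""
    engine = engine or ViennaEngine()
    seq = transcript.sequence if isinstance(transcript, TranscriptModel) else to_rna(transcript)
    n = window_count(len(seq), window, step)
    energies = [
        engine.duplex_energy(seq[i * step : i * step + window], asd_sequence)
        for i in range(n)
    ]
    return EnergyProfile(window_size=window, step=step, energies=energies)


def affected_windows(
    transcript: TranscriptModel,
    variant: MutantVariant,
    window: int = 10,
    step: int = 1,
) -> list[int]:
    """Indices of windows overlapping the mutated codon (0-based)."""
    lo, hi = transcript.codon_span(variant.position)
    n = window_count(len(transcript.sequence), window, step)
    out = []
    for i in range(n):
        w_lo, w_hi = i * step + 1, i * step + window
        if w_lo <= hi and w_hi >= lo:
            out.append(i)
    return out


def delta_asd(
    mutant_profile: EnergyProfile,
    wt_profile: EnergyProfile,
    affected: Sequence[int] | None = None,
) -> float:
    """Average mutant-minus-WT window energy difference.

    By default the average runs over the affected windows only (those whose
    sequence can differ between mutant and WT); ``affected=None`` with no
    restriction averages all windows.  Positive values mean the mutant
    shows weaker anti-SD pairing, i.e. less predicted pausing, than WT.
    """
    if (
        mutant_profile.window_size != wt_profile.window_size
        or mutant_profile.step != wt_profile.step
        or len(mutant_profile) != len(wt_profile)
    ):
        raise ValueError("profiles have mismatched window geometry")
    diffs = [m - w for m, w in zip(mutant_profile.energies, wt_profile.energies)]
    if affected is not None:
        if not affected:
            raise ValueError("empty affected-window set")
        diffs = [diffs[i] for i in affected]
    return float(sum(diffs) / len(diffs))


def delta_asd_for_variant(
    operon_sequence: str,
    variant: MutantVariant,
    engine: ViennaEngine | None = None,
    window: int = 10,
    step: int = 1,
    cds_offset: int = DEFAULT_UPSTREAM + 1,
    cds_length: int | None = None,
    mode: str = "affected",
) -> float:
    """End-to-end delta-aSD for a single variant against the WT transcript."""
    engine = engine or ViennaEngine()
    wt = build_transcript(operon_sequence, None, cds_offset, cds_length)
    mut = build_transcript(operon_sequence, variant, cds_offset, cds_length)
    wt_prof = asd_window_profile(wt, engine, window, step)
    mut_prof = asd_window_profile(mut, engine, window, step)
    if mode == "affected":
        idx = affected_windows(wt, variant, window, step)
    elif mode == "all":
        idx = None
    else:
        raise ValueError(f"unknown delta-aSD mode {mode!r}")
    return delta_asd(mut_prof, wt_prof, idx)


def mfe_window_average(
    transcript: TranscriptModel | str,
    engine: ViennaEngine | None = None,
    window: int = 30,
    step: int = 1,
) -> float:
    """Mean single-strand MFE over all sliding windows of the transcript."""
    engine = engine or ViennaEngine()
    seq = transcript.sequence if isinstance(transcript, TranscriptModel) else to_rna(transcript)
    n = window_count(len(seq), window, step)
    energies = [engine.mfe(seq[i * step : i * step + window]) for i in range(n)]
    return float(sum(energies) / n)


def delta_mfe(mutant_avg: float, wt_avg: float) -> float:
    """avgMFE(mutant) - avgMFE(WT); positive = destabilised mutant transcript."""
    return float(mutant_avg - wt_avg)


def rbs_accessibility(
    region_sequence: str,
    sd_span: tuple[int, int],
    engine: ViennaEngine | None = None,
) -> float:
    """Fraction of SD-span bases unpaired in the region's MFE structure.

    ``sd_span`` is a 1-based inclusive index range within the region; 1.0
    means a fully accessible (unstructured) ribosome-binding site.
    """
    engine = engine or ViennaEngine()
    seq = to_rna(region_sequence)
    lo, hi = sd_span
    if not (1 <= lo <= hi <= len(seq)):
        raise ValueError(f"SD span {sd_span} outside region of length {len(seq)}")
    structure = engine.mfe_structure(seq)
    span = structure[lo - 1 : hi]
    return span.count(".") / len(span)
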
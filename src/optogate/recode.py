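"""Synonymous recoding of early codons and 5' transcript-window folding.

Heterologous genes often translate poorly because the ribosome binding
site and the first codons fold into stable mRNA secondary structure. A
simple, effective debugging heuristic is to synonymously recode the
first 15 codons of the ORF to reduce GC content and increase AU content
(preferring A over U), lowering the pairing potential of the 5' window,
and to score the change by the minimum folding free energy of the
transcript from the transcription start site through ORF nucleotide 90.

The preference is formalized as a deterministic lexicographic score per
codon family: (GC count ascending, A count descending, U count
descending, alphabetic order as the final tie-break). The start codon
is never altered (initiation-codon identity is functional even when a
synonym exists) and stop codons are never introduced — synonymous
substitution cannot create one.

Folding backends are pluggable (any ``seq -> kcal/mol`` callable on RNA
strings). The built-in model is a simplified nested-pairing (Nussinov
style) minimum-energy fold: GC -3, AU -2, GU -1 kcal/mol per pair,
minimum hairpin loop 3 nt, no pseudoknots. A ViennaRNA backend is
provided when the bindings are importable; thermodynamic-model energies
differ from the built-in model's and neither is required to match any
external reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "RecodedORF",
    "TranscriptWindow",
    "recode_first15",
    "window_energy",
    "recode_report",
    "nussinov_energy",
    "vienna_energy",
    "default_backend",
]

# bacterial/archaeal code (NCBI table 11): same sense codons as the standard
# code but with the full set of bacterial initiation codons (ATG/GTG/TTG/...)
_STANDARD = CodonTable.unambiguous_dna_by_id[11]
_START_CODONS = set(_STANDARD.start_codons)

# pair energies (kcal/mol) of the built-in nested-pairing model
_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
_MIN_LOOP = 3  # unpaired nucleotides enclosed by a pair, minimum


@lru_cache(maxsize=1)
def _synonym_map() -> dict[str, tuple[str, ...]]:
    families: dict[str, list[str]] = {}
    for codon, aa in _STANDARD.forward_table.items():
        families.setdefault(aa, []).append(codon)
    return {
        codon: tuple(sorted(families[aa]))
        for codon, aa in _STANDARD.forward_table.items()
    }


def _codon_score(codon: str) -> tuple[int, int, int, str]:
    """Lower is preferred: (GC count, -A count, -U count, codon)."""
    gc = codon.count("G") + codon.count("C")
    return (gc, -codon.count("A"), -codon.count("T"), codon)


def _best_synonym(codon: str) -> str:
    return min(_synonym_map()[codon], key=_codon_score)


@dataclass(frozen=True)
class RecodedORF:
    """Original and recoded coding sequence with substitution records."""

    original_sequence: str
    recoded_sequence: str
    substitutions: tuple[tuple[int, str, str], ...]  # (codon index 1-based, from, to)
    window_energy_before: float | None = None
    window_energy_after: float | None = None

    def __post_init__(self) -> None:
        if len(self.original_sequence) != len(self.recoded_sequence):
            raise ValueError("sequences must have equal length")
        if len(self.original_sequence) % 3 != 0:
            raise ValueError("sequence length must be divisible by 3")


@dataclass(frozen=True)
class TranscriptWindow:
    """Transcript from the +1 transcription start through ORF nucleotide 90.

    ``tss_offset`` counts 5'UTR nucleotides preceding the start codon;
    ORFs shorter than 90 nt truncate the window at the ORF end.
    """

    sequence: str
    tss_offset: int

    @classmethod
    def build(cls, utr: str, orf: str) -> "TranscriptWindow":
        utr = utr.upper()
        orf = orf.upper()
        _check_alphabet(utr + orf)
        return cls(sequence=utr + orf[:90], tss_offset=len(utr))


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")


def recode_first15(orf: str, n_codons: int = 15) -> RecodedORF:
    """Synonymously recode the first ``n_codons`` codons of an ORF.

    Each of codons 1..15 (fewer for short ORFs; the final stop and the
    start codon are left untouched) is replaced by the synonym
    minimizing (GC count, -A count, -U count, alphabetic). The protein
    sequence is preserved by construction and the operation is
    idempotent.
    """
    orf = orf.upper()
    _check_alphabet(orf)
    if len(orf) < 3 or len(orf) % 3 != 0:
        raise ValueError("ORF length must be a positive multiple of 3")
    codons = [orf[i:i + 3] for i in range(0, len(orf), 3)]
    if codons[0] not in _START_CODONS:
        raise ValueError(f"ORF must begin with a start codon, got {codons[0]!r}")
    for idx, c in enumerate(codons[:-1]):
        if c in _STANDARD.stop_codons:
            raise ValueError(f"internal stop codon {c!r} at codon {idx + 1}")

    last = len(codons) - 1 if codons[-1] in _STANDARD.stop_codons else len(codons)
    subs: list[tuple[int, str, str]] = []
    new = list(codons)
    for i in range(1, min(n_codons, last)):  # codon 1 (start) never altered
        repl = _best_synonym(codons[i])
        if repl != codons[i]:
            new[i] = repl
            subs.append((i + 1, codons[i], repl))
    recoded = "".join(new)
    assert str(Seq(orf).translate()) == str(Seq(recoded).translate())
    return RecodedORF(
        original_sequence=orf,
        recoded_sequence=recoded,
        substitutions=tuple(subs),
    )


def nussinov_energy(rna: str) -> float:
    """Minimum energy over nested pairings of the built-in model.

    Dynamic program over intervals: a base is unpaired or pairs with a
    partner at least ``_MIN_LOOP + 1`` positions away, splitting the
    interval. Always <= 0; exactly 0 when no canonical pair is possible.
    """
    s = rna.upper().replace("T", "U")
    n = len(s)
    if n < _MIN_LOOP + 2:
        return 0.0
    E = [[0.0] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i][j - 1]  # j unpaired
            for k in range(i, j - _MIN_LOOP):
                e = _PAIR_ENERGY.get((s[k], s[j]))
                if e is None:
                    continue
                left = E[i][k - 1] if k > i else 0.0
                inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                cand = left + e + inner
                if cand < best:
                    best = cand
            E[i][j] = best
    return E[0][n - 1]


def vienna_energy(rna: str) -> float:
    """Thermodynamic MFE via the ViennaRNA bindings (optional backend)."""
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "ViennaRNA bindings are not installed; use the built-in "
            "nussinov_energy backend or install ViennaRNA"
        ) from exc
    _, mfe = RNA.fold(rna.upper().replace("T", "U"))
    return min(float(mfe), 0.0)


def default_backend() -> Callable[[str], float]:
    return nussinov_energy


def window_energy(
    window: TranscriptWindow, backend: Callable[[str], float] | None = None
) -> float:
    """Folding free energy (kcal/mol) of the transcript window.

    DNA input is transcribed T -> U before folding. The result is <= 0;
    0 means the window admits no canonical pair.
    """
    if backend is None:
        backend = default_backend()
    rna = window.sequence.upper().replace("T", "U")
    return float(backend(rna))


def recode_report(
    utr: str,
    orf: str,
    backend: Callable[[str], float] | None = None,
    n_codons: int = 15,
) -> RecodedORF:
    """Recode the ORF and score both 5' windows with the same UTR."""
    rec = recode_first15(orf, n_codons=n_codons)
    before = window_energy(TranscriptWindow.build(utr, rec.original_sequence), backend)
    after = window_energy(TranscriptWindow.build(utr, rec.recoded_sequence), backend)
    return RecodedORF(
        original_sequence=rec.original_sequence,
        recoded_sequence=rec.recoded_sequence,
        substitutions=rec.substitutions,
        window_energy_before=before,
        window_energy_after=after,
    )
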
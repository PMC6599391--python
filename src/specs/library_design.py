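"""Design of a barcoded synthetic promoter library from TF binding-site motifs.

Each transcription-factor binding site (TF-BS) is collapsed to its consensus
sequence (per-position argmax of the position weight matrix), taken on both
strands, and tiled as a tandem repeat -- ``k`` copies of (TF-BS + 3 bp spacer)
where ``k = 129 // (L + 3)`` -- so the variable promoter region never exceeds
the 129 bp synthesis budget of a ~150 bp pooled oligo. Every construct carries
a unique random 17 bp barcode, and the 3' flank contains the AscI restriction
site used downstream to delimit the variable region in sequencing reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

NUCLEOTIDES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Design constants. The spacer and flanks are configurable constants of the
# design, fixed here so library builds are deterministic; the AscI recognition
# sequence (GGCGCGCC) sits at the 5' end of the 3' flank.
VARIABLE_REGION_BUDGET = 129  # bp available for the tandem TF-BS repeat
SPACER = "CGT"                # neutral 3 bp spacer between repeat units
BARCODE_LENGTH = 17
ASCI_SITE = "GGCGCGCC"
FLANK_5 = "ACTGGCCGCTTCACTG"
FLANK_3 = ASCI_SITE + "TCTAGAGGGTATATAATGGAAGCTCGACTTCCAG"  # AscI + minimal-promoter stub


class MotifValidationError(ValueError):
    """Raised when a PWM fails validation (bad row sums, shape, duplicates)."""


@dataclass(frozen=True)
class MotifMatrix:
    """A position weight matrix: per-position nucleotide probabilities.

    ``probs`` has shape (L, 4) in A, C, G, T column order; every row must be a
    probability distribution and motifs shorter than 4 bp are rejected.
    """

    motif_id: str
    tf_name: str
    probs: np.ndarray
    species: str = "unknown"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise MotifValidationError(
                f"motif {self.motif_id!r}: expected an L x 4 matrix, got shape {probs.shape}"
            )
        if probs.shape[0] < 4:
            raise MotifValidationError(
                f"motif {self.motif_id!r}: motif length {probs.shape[0]} < 4"
            )
        if np.any(probs < 0) or np.any(probs > 1):
            raise MotifValidationError(
                f"motif {self.motif_id!r}: probabilities outside [0, 1]"
            )
        sums = probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if bad.size:
            raise MotifValidationError(
                f"motif {self.motif_id!r}: row {bad[0]} sums to {sums[bad[0]]:.6g}, not 1"
            )

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class PromoterConstruct:
    """One designed promoter: a tandem TF-BS repeat plus barcode and flanks."""

    construct_id: str
    source_motif_id: str
    strand: str  # "forward" | "revcomp"
    tfbs: str
    repeat_count: int
    spacer: str
    barcode: str
    variable_region: str
    full_oligo: str

    def __post_init__(self) -> None:
        assert self.variable_region == (self.tfbs + self.spacer) * self.repeat_count
        assert len(self.variable_region) <= VARIABLE_REGION_BUDGET
        assert len(self.barcode) == BARCODE_LENGTH


@dataclass
class LibraryReference:
    """The indexed set of designed constructs.

    ``index`` maps each variable-region sequence to its construct_id and is the
    lookup used when assigning sequencing reads back to library members.
    """

    constructs: list[PromoterConstruct]
    index: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {}
        for c in self.constructs:
            if c.variable_region in self.index:
                raise ValueError(
                    f"variable region of {c.construct_id} collides with "
                    f"{self.index[c.variable_region]}"
                )
            self.index[c.variable_region] = c.construct_id

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    def by_id(self, construct_id: str) -> PromoterConstruct:
        for c in self.constructs:
            if c.construct_id == construct_id:
                return c
        raise KeyError(construct_id)

    # ---- serialization ----------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        """Write the variable-region reference as FASTA (one record/construct)."""
        with open(path, "w") as fh:
            for c in self.constructs:
                fh.write(f">{c.construct_id}\n{c.variable_region}\n")

    def to_design_table(self, path: str | Path) -> None:
        """Write the TSV design table (id, tf, strand, L, k, barcode, oligo)."""
        with open(path, "w") as fh:
            fh.write(
                "construct_id\tsource_motif_id\ttf_name\tstrand\ttfbs\t"
                "tfbs_length\trepeat_count\tbarcode\tfull_oligo\n"
            )
            for c in self.constructs:
                tf = c.construct_id.rsplit("_", 1)[0]
                fh.write(
                    f"{c.construct_id}\t{c.source_motif_id}\t{tf}\t{c.strand}\t"
                    f"{c.tfbs}\t{len(c.tfbs)}\t{c.repeat_count}\t{c.barcode}\t"
                    f"{c.full_oligo}\n"
                )


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def consensus_from_pwm(motif: MotifMatrix) -> str:
    """Consensus sequence: per-position maximum-probability nucleotide.

    Ties resolve to the alphabetically first nucleotide (A < C < G < T), so
    the consensus is deterministic. An all-uniform row yields 'A'.
    """
    # np.argmax returns the first maximal index; columns are in A,C,G,T order,
    # so the tie-break is alphabetical by construction.
    idx = np.argmax(motif.probs, axis=1)
    return "".join(NUCLEOTIDES[i] for i in idx)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T sequence."""
    bad = set(seq.upper()) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def tandem_repeat_count(tfbs_length: int) -> int:
    """Number of (TF-BS + spacer) units fitting the 129 bp variable region.

    ``k = floor(129 / (L + 3))``; floor keeps the repeat inside the synthesis
    budget. Returns 0 (un-designable) for L > 126, where not even one unit
    fits.
    """
    if tfbs_length < 1:
        raise ValueError(f"tfbs_length must be >= 1, got {tfbs_length}")
    return VARIABLE_REGION_BUDGET // (tfbs_length + len(SPACER))


# ---------------------------------------------------------------------------
# Library assembly
# ---------------------------------------------------------------------------

_MAX_BARCODE_RETRIES = 1000


def _draw_barcode(rng: np.random.Generator, used: set[str]) -> str:
    for _ in range(_MAX_BARCODE_RETRIES):
        bc = "".join(rng.choice(list(NUCLEOTIDES), size=BARCODE_LENGTH))
        if ASCI_SITE in bc or bc in used:
            continue
        return bc
    raise RuntimeError("could not draw a unique AscI-free barcode; library too large?")


def build_library(motifs: Iterable[MotifMatrix], seed: int) -> LibraryReference:
    """Assemble the barcoded library reference from validated motifs.

    For every motif the forward consensus and its reverse complement each
    yield one construct, after deduplicating consensus sequences across the
    whole collection (a palindromic consensus yields a single construct).
    Barcodes are uniform random 17-mers, rejected on AscI content or
    collision; the build is reproducible for a fixed seed.
    """
    motifs = list(motifs)
    seen_ids: set[str] = set()
    for m in motifs:
        if m.motif_id in seen_ids:
            raise MotifValidationError(f"duplicate motif_id {m.motif_id!r}")
        seen_ids.add(m.motif_id)

    rng = np.random.default_rng(seed)
    used_barcodes: set[str] = set()
    seen_consensi: set[str] = set()
    constructs: list[PromoterConstruct] = []
    skipped: list[str] = []

    for m in motifs:
        consensus = consensus_from_pwm(m)
        for strand, tfbs in (("forward", consensus),
                             ("revcomp", reverse_complement(consensus))):
            if tfbs in seen_consensi:
                continue
            seen_consensi.add(tfbs)
            k = tandem_repeat_count(len(tfbs))
            if k == 0:
                skipped.append(m.motif_id)
                continue
            barcode = _draw_barcode(rng, used_barcodes)
            used_barcodes.add(barcode)
            variable = (tfbs + SPACER) * k
            suffix = "fwd" if strand == "forward" else "rc"
            constructs.append(PromoterConstruct(
                construct_id=f"{m.tf_name}_{m.motif_id}_{suffix}",
                source_motif_id=m.motif_id,
                strand=strand,
                tfbs=tfbs,
                repeat_count=k,
                spacer=SPACER,
                barcode=barcode,
                variable_region=variable,
                full_oligo=FLANK_5 + variable + barcode + FLANK_3,
            ))
    library = LibraryReference(constructs)
    if skipped:
        library.skipped_motifs = skipped  # type: ignore[attr-defined]
    return library


def random_motifs(n: int, seed: int, length_range: tuple[int, int] = (6, 18),
                  concentration: float = 0.3) -> list[MotifMatrix]:
    """Draw synthetic PWMs (Dirichlet rows) for simulation studies.

    Low ``concentration`` gives sharply peaked positions, like real binding
    motifs; lengths are uniform over ``length_range``.
    """
    rng = np.random.default_rng(seed)
    motifs = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        probs = rng.dirichlet([concentration] * 4, size=L)
        motifs.append(MotifMatrix(motif_id=f"M{i:04d}", tf_name=f"TF{i:04d}",
                                  probs=probs, species="synthetic"))
    return motifs


# ---------------------------------------------------------------------------
# Motif I/O
# ---------------------------------------------------------------------------

def read_motifs_tsv(path: str | Path) -> list[MotifMatrix]:
    """Read motifs from the simple tabular format.

    Blocks start with a header line ``>motif_id<TAB>tf_name[<TAB>species]``
    followed by one probability row per position (A C G T, tab- or
    space-separated). Rows are validated, not renormalized.
    """
    motifs: list[MotifMatrix] = []
    header: tuple[str, str, str] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is not None:
            motif_id, tf_name, species = header
            motifs.append(MotifMatrix(motif_id, tf_name, np.array(rows), species))
        header, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                if len(parts) < 2:
                    parts = line[1:].split()
                if len(parts) < 2:
                    raise MotifValidationError(
                        f"{path}:{lineno}: header needs motif_id and tf_name"
                    )
                header = (parts[0], parts[1], parts[2] if len(parts) > 2 else "unknown")
            else:
                if header is None:
                    raise MotifValidationError(f"{path}:{lineno}: matrix row before header")
                rows.append([float(x) for x in line.split()])
    flush()
    return motifs


def read_motifs_jaspar(path: str | Path) -> list[MotifMatrix]:
    """Read JASPAR-format count matrices, row-normalizing counts to probabilities."""
    from Bio import motifs as bio_motifs

    out: list[MotifMatrix] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[nt] for nt in NUCLEOTIDES], dtype=float).T
            totals = counts.sum(axis=1, keepdims=True)
            if np.any(totals == 0):
                raise MotifValidationError(f"motif {m.matrix_id}: zero-count position")
            out.append(MotifMatrix(
                motif_id=m.matrix_id or m.name,
                tf_name=m.name or m.matrix_id,
                probs=counts / totals,
            ))
    return out


def read_motifs(path: str | Path) -> list[MotifMatrix]:
    """Read motifs, sniffing JASPAR count blocks vs. the probability TSV."""
    # JASPAR lines look like "A  [ 3 5 0 ]"; the TSV dialect has no brackets.
    text = Path(path).read_text()
    if "[" in text:
        return read_motifs_jaspar(path)
    return read_motifs_tsv(path)
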
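"""The three sequence-based mitotype assays.

1. **cytb–BglII RFLP (in silico).**  The mitochondrial cytochrome *b*
   amplicon of African-lineage honey bees lacks the BglII recognition site
   (AGATCT) and runs as a single band on a gel; European/Middle Eastern
   mitotypes carry the site and give two bands.  :func:`digest` cuts a
   sequence at every exact motif occurrence (cut after the first base,
   matching BglII's A^GATCT overhang) and drops fragments too short to be
   visible; :func:`rflp_mitotype` reads the band count.

2. **COI barcode diagnostic SNP.**  A single C/T polymorphism in the COI
   DNA-barcode region (mitogenome position 2382) separates African (C)
   from European (T) mitotypes.  :func:`coi_snp_call` aligns a query
   barcode to the panel's annotated reference and reads the base paired
   with the diagnostic coordinate.

3. **COI–COII spacer lineage.**  :func:`spacer_lineage` assigns a spacer
   sequence to the nearest of the panel's A/C/M/O exemplars by normalized
   edit distance (nearest-reference assignment in place of full
   phylogenetic placement).

The bundled default panel is a synthetic stand-in (see
``data/panel/panel.json``); users typing real material should point
:func:`load_panel` at a directory of real reference sequences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import edlib
import pandas as pd
from Bio import Align

from .types import (
    Call,
    DomainError,
    Marker,
    MarkerCall,
    Specimen,
)

_VALID_SEQ = set("ACGTN")
_DEFAULT_MIN_VISIBLE_BP = 50


@dataclass(frozen=True)
class ReferencePanel:
    """Reference material for the three assays.

    ``diagnostic_offset`` is the 0-based position of the C/T diagnostic
    site within ``coi_reference`` (derived from the mitogenome coordinate
    and the fragment start annotation).  ``spacer_exemplars`` maps lineage
    labels (conventionally A, C, M, O) to exemplar sequences.
    """

    coi_reference: str
    diagnostic_offset: int
    spacer_exemplars: Mapping[str, str]
    restriction_motif: str = "AGATCT"
    diagnostic_position_mtdna: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.diagnostic_offset < len(self.coi_reference):
            raise DomainError(
                f"diagnostic offset {self.diagnostic_offset} outside the "
                f"{len(self.coi_reference)} bp COI reference"
            )
        if len(self.restriction_motif) < 4 or set(self.restriction_motif) - set("ACGT"):
            raise DomainError(
                f"restriction motif {self.restriction_motif!r} must be >= 4 bp of ACGT"
            )
        seqs = list(self.spacer_exemplars.values())
        if len(set(seqs)) != len(seqs):
            raise DomainError("spacer exemplars must be pairwise distinct")


def load_panel(panel_dir: str | Path) -> ReferencePanel:
    """Load a reference panel from a directory (panel.json + FASTA files)."""
    from .data_io import read_fasta

    panel_dir = Path(panel_dir)
    meta = json.loads((panel_dir / "panel.json").read_text())
    coi_records = read_fasta(panel_dir / meta["coi_reference_fasta"])
    if len(coi_records) != 1:
        raise DomainError("COI reference FASTA must hold exactly one record")
    coi = coi_records[0][1]
    exemplars = dict(read_fasta(panel_dir / meta["spacer_exemplars_fasta"]))
    offset = meta["diagnostic_position_mtdna"] - meta["coi_fragment_start_mtdna"]
    return ReferencePanel(
        coi_reference=coi,
        diagnostic_offset=offset,
        spacer_exemplars=exemplars,
        restriction_motif=meta.get("restriction_motif", "AGATCT"),
        diagnostic_position_mtdna=meta["diagnostic_position_mtdna"],
    )


def default_panel() -> ReferencePanel:
    """The bundled synthetic stand-in panel."""
    with resources.as_file(resources.files("afribee") / "data" / "panel") as p:
        return load_panel(p)


def _validate_seq(seq: str, what: str) -> str:
    if not seq:
        raise DomainError(f"{what} must be non-empty")
    seq = seq.upper()
    bad = set(seq) - _VALID_SEQ
    if bad:
        raise DomainError(f"{what} contains non-ACGTN characters: {sorted(bad)}")
    return seq


def digest(
    seq: str,
    motif: str = "AGATCT",
    min_visible_bp: int = _DEFAULT_MIN_VISIBLE_BP,
    cut_offset: int = 1,
) -> list[int]:
    """Cut ``seq`` at every exact occurrence of ``motif``; return visible band lengths.

    The cut falls ``cut_offset`` bases after the start of each motif match
    (default 1: BglII cuts A^GATCT).  Fragments shorter than
    ``min_visible_bp`` are suppressed, emulating bands that run off a gel.
    With ``min_visible_bp=0`` the returned lengths sum to ``len(seq)``.
    Degenerate bases (N) never match the motif: only exact ACGT matches cut.
    """
    seq = _validate_seq(seq, "sequence")
    if set(motif) - set("ACGT"):
        raise DomainError(f"motif {motif!r} must contain only ACGT")
    if not 0 <= cut_offset <= len(motif):
        raise DomainError(f"cut_offset {cut_offset} outside [0, {len(motif)}]")

    cuts = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            break
        cuts.append(i + cut_offset)
        start = i + 1  # allow overlapping occurrences of self-overlapping motifs
    bounds = [0, *cuts, len(seq)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return [f for f in fragments if f >= min_visible_bp]


def rflp_mitotype(
    seq: str,
    panel: Optional[ReferencePanel] = None,
    min_visible_bp: int = _DEFAULT_MIN_VISIBLE_BP,
) -> MarkerCall:
    """Score a cytb amplicon as African (one band) or European (two bands).

    Any other visible band count yields an indeterminate call carrying the
    band lengths as evidence.
    """
    motif = panel.restriction_motif if panel is not None else "AGATCT"
    if not 100 <= len(seq) <= 2000:
        warnings.warn(
            f"cytb amplicon length {len(seq)} bp outside the plausible "
            "100-2000 bp range",
            stacklevel=2,
        )
    bands = digest(seq, motif, min_visible_bp)
    evidence = f"bands={bands}"
    if len(bands) == 1:
        return MarkerCall(Marker.CYTB_RFLP, Call.AFRICAN, evidence, True)
    if len(bands) == 2:
        return MarkerCall(Marker.CYTB_RFLP, Call.EUROPEAN, evidence, True)
    return MarkerCall(Marker.CYTB_RFLP, Call.INDETERMINATE, evidence, False)


def _make_aligner() -> Align.PairwiseAligner:
    # Overlap alignment: end gaps free on both sequences, so a barcode
    # fragment starting at an arbitrary offset maps cleanly onto the
    # reference without terminal-gap penalties.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aligner.end_insertion_score = 0.0  # free end gaps in the reference
    aligner.end_deletion_score = 0.0  # free end gaps in the query
    return aligner


def coi_snp_call(
    barcode: str,
    panel: ReferencePanel,
    min_identity: float = 0.90,
) -> MarkerCall:
    """Call the diagnostic COI SNP: C → African, T → European.

    The query barcode is aligned to the panel's COI reference with free
    end gaps; the query base paired with the annotated diagnostic
    coordinate is read.  A gap at the site, an uncovered site, a base
    other than C/T, or alignment identity below ``min_identity`` over the
    aligned (non-end-gap) region yields an indeterminate call.
    """
    barcode = _validate_seq(barcode, "COI barcode")
    if len(barcode) < 100:
        warnings.warn(
            f"COI barcode length {len(barcode)} bp is short for a barcode fragment",
            stacklevel=2,
        )
    aligner = _make_aligner()
    alignment = aligner.align(panel.coi_reference, barcode)[0]
    ref_idx, query_idx = alignment.indices  # -1 marks gaps

    matches = 0
    aligned_cols = 0
    diag_query_idx: Optional[int] = None
    for col in range(ref_idx.shape[0]):
        r, q = int(ref_idx[col]), int(query_idx[col])
        if r >= 0 and q >= 0:
            aligned_cols += 1
            if panel.coi_reference[r] == barcode[q]:
                matches += 1
        if r == panel.diagnostic_offset:
            diag_query_idx = q if q >= 0 else None

    identity = matches / aligned_cols if aligned_cols else 0.0
    if diag_query_idx is None:
        return MarkerCall(
            Marker.COI_SNP,
            Call.INDETERMINATE,
            f"position not covered (identity={identity:.3f})",
            False,
        )
    base = barcode[diag_query_idx]
    evidence = f"base={base} at diagnostic site, identity={identity:.3f}"
    if identity < min_identity:
        return MarkerCall(
            Marker.COI_SNP,
            Call.INDETERMINATE,
            f"identity {identity:.3f} below {min_identity:.2f} ({evidence})",
            False,
        )
    if base == "C":
        return MarkerCall(Marker.COI_SNP, Call.AFRICAN, evidence, True)
    if base == "T":
        return MarkerCall(Marker.COI_SNP, Call.EUROPEAN, evidence, True)
    return MarkerCall(Marker.COI_SNP, Call.INDETERMINATE, evidence, False)


def spacer_lineage(seq: str, panel: ReferencePanel) -> MarkerCall:
    """Assign a COI–COII spacer sequence to the nearest panel exemplar.

    Distance is global edit distance normalized by alignment length; the
    call is the lineage of the unique minimum.  A tie for the minimum
    yields an indeterminate call.  Evidence records all distances.
    """
    seq = _validate_seq(seq, "spacer sequence")
    if len(seq) < 50:
        warnings.warn(
            f"spacer sequence length {len(seq)} bp is short", stacklevel=2
        )
    distances: dict[str, float] = {}
    for lineage, exemplar in panel.spacer_exemplars.items():
        res = edlib.align(seq, exemplar, mode="NW", task="path")
        alen = sum(
            int(n) for n, _ in _parse_cigar(res["cigar"])
        )
        distances[lineage] = res["editDistance"] / alen
    evidence = "distances " + " ".join(
        f"{lin}={d:.4f}" for lin, d in sorted(distances.items())
    )
    best = min(distances.values())
    winners = [lin for lin, d in distances.items() if d <= best + 1e-12]
    if len(winners) != 1:
        return MarkerCall(
            Marker.SPACER_LINEAGE,
            Call.INDETERMINATE,
            f"tie between {sorted(winners)}; {evidence}",
            False,
        )
    call = Call(f"lineage_{winners[0]}")
    return MarkerCall(Marker.SPACER_LINEAGE, call, evidence, True)


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


@dataclass
class ConcordanceResult:
    """Cross-tabulations of mitotype class for every pair of markers."""

    tables: dict[tuple[Marker, Marker], pd.DataFrame] = field(default_factory=dict)

    def concordant(self, pair: tuple[Marker, Marker]) -> bool:
        """True when the pair's African/European off-diagonal cells are zero."""
        t = self.tables[pair]
        off = 0
        for a in t.index:
            for b in t.columns:
                if a != b:
                    off += int(t.loc[a, b])
        return off == 0

    @property
    def all_concordant(self) -> bool:
        return all(self.concordant(p) for p in self.tables)


def concordance_table(specimens: Iterable[Specimen]) -> ConcordanceResult:
    """Cross-tabulate African/European classes between every marker pair.

    Each specimen must carry confident calls for at least two markers.
    Spacer-lineage calls are binarized (A → African; C/M/O → European) so
    all pairs tabulate on the same two classes.
    """
    specimens = list(specimens)
    if not specimens:
        raise DomainError("concordance_table requires at least one specimen")

    rows = []
    for sp in specimens:
        classes: dict[Marker, str] = {}
        for c in sp.calls:
            if c.confident and c.mitotype is not None:
                classes[c.marker] = c.mitotype.value
        if len(classes) < 2:
            raise DomainError(
                f"specimen {sp.specimen_id} has {len(classes)} confident "
                "marker calls; at least 2 required for concordance"
            )
        rows.append((sp.specimen_id, classes))

    markers = sorted(
        {m for _, classes in rows for m in classes}, key=lambda m: m.value
    )
    result = ConcordanceResult()
    levels = [Call.AFRICAN.value, Call.EUROPEAN.value]
    for i, m1 in enumerate(markers):
        for m2 in markers[i + 1 :]:
            pairs = [
                (classes[m1], classes[m2])
                for _, classes in rows
                if m1 in classes and m2 in classes
            ]
            df = pd.crosstab(
                pd.Categorical([a for a, _ in pairs], categories=levels),
                pd.Categorical([b for _, b in pairs], categories=levels),
                dropna=False,
            )
            df.index.name = m1.value
            df.columns.name = m2.value
            result.tables[(m1, m2)] = df
    return result
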
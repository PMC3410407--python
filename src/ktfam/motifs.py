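"""Degenerate protein motif compilation, scanning and family classification.

Ten class-specific consensus motifs (three for K+ channels, two for HKT
transporters, five for HAK transporters) are shipped as a plain-text
library in a dash-separated dialect: each position is either ``x`` (any
residue), a single residue letter, or a bracketed allowed set such as
``[S,T]``.  Scanning is exact positional matching of every window
(overlaps allowed), i.e. a PROSITE-style search without indels.

Classification into candidate families uses configurable co-occurrence
rules; the shipped defaults require three of the five HAK motifs, both
HKT motifs, or the pore motif (motif 1, the selectivity-filter region)
for a channel call.  The number of non-overlapping pore motifs separates
single-pore (Shaker-like, voltage-gated) from tandem-pore (TPK) channel
subunits.  X never satisfies a restricted position; the wildcard matches
any letter including X.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .seqio import AMINO_ACIDS, ProteinRecord

FAMILY_CLASSES = ("CHANNEL", "HKT", "HAK")


class MotifCompileError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif.

    ``positions`` holds one entry per motif position: ``None`` for the
    wildcard, otherwise a frozenset of allowed residues.
    """

    motif_id: int
    family_class: str
    positions: tuple
    source_text: str

    def __len__(self) -> int:
        return len(self.positions)

    def render(self) -> str:
        """Reproduce the motif string (canonical form, per-position source order)."""
        parts = []
        for raw in self.source_text.split("-"):
            token = raw.strip()
            if token.lower() == "x":
                parts.append("x")
            elif token.startswith("["):
                letters = [t.strip().upper() for t in token[1:-1].split(",")]
                parts.append("[" + ",".join(letters) + "]")
            else:
                parts.append(token.upper())
        return "-".join(parts)

    def matches_at(self, sequence: str, start: int) -> bool:
        if start < 0 or start + len(self.positions) > len(sequence):
            return False
        for offset, allowed in enumerate(self.positions):
            if allowed is None:
                continue
            if sequence[start + offset] not in allowed:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_id: int
    start: int
    end: int
    matched: str


@dataclass(frozen=True)
class ClassificationRules:
    """Co-occurrence rules turning motif hits into a family call."""

    hak_min: int = 3           # of the five HAK motifs (6-10)
    hkt_require_both: bool = True
    channel_min_pore: int = 1  # motif-1 (pore) hits required for CHANNEL


@dataclass(frozen=True)
class FamilyCall:
    protein_id: str
    family: str  # HAK | HKT | CHANNEL | UNCLASSIFIED
    channel_pore_count: int
    channel_subtype: str  # SINGLE_PORE | TANDEM_PORE | MULTI | NA
    evidence: tuple
    motif_ids_matched: frozenset


def compile_motif(source_text: str, motif_id: int = 0, family_class: str = "CHANNEL") -> MotifPattern:
    """Compile a dash-separated degenerate motif string.

    Case-insensitive input; unknown tokens, empty brackets or non-standard
    residue letters raise MotifCompileError naming the position.
    """
    tokens = source_text.strip().split("-")
    if not tokens or tokens == [""]:
        raise MotifCompileError("empty motif")
    positions = []
    for i, raw in enumerate(tokens, start=1):
        token = raw.strip().upper()
        if token == "X":
            positions.append(None)
        elif token.startswith("[") and token.endswith("]"):
            letters = [t.strip() for t in token[1:-1].split(",") if t.strip()]
            if not letters:
                raise MotifCompileError(f"position {i}: empty bracket")
            bad = [l for l in letters if l not in AMINO_ACIDS]
            if bad:
                raise MotifCompileError(f"position {i}: non-standard residue {bad[0]!r}")
            positions.append(frozenset(letters))
        elif len(token) == 1 and token in AMINO_ACIDS:
            positions.append(frozenset(token))
        else:
            raise MotifCompileError(f"position {i}: unknown token {raw!r}")
    return MotifPattern(
        motif_id=motif_id,
        family_class=family_class,
        positions=tuple(positions),
        source_text=source_text.strip(),
    )


def load_motif_library() -> list[MotifPattern]:
    """The ten packaged screening motifs, in printed order."""
    text = resources.files("ktfam.data").joinpath("motifs.txt").read_text()
    library = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        motif_id, family_class, motif = line.split("\t")
        library.append(compile_motif(motif, motif_id=int(motif_id), family_class=family_class))
    if len(library) != 10:
        raise MotifCompileError("packaged motif library must contain 10 motifs")
    return library


def scan(protein: ProteinRecord, pattern: MotifPattern) -> list[MotifHit]:
    """All (possibly overlapping) windows satisfying the pattern, by start."""
    hits = []
    m = len(pattern)
    seq = protein.sequence
    for start in range(len(seq) - m + 1):
        if pattern.matches_at(seq, start):
            hits.append(
                MotifHit(
                    protein_id=protein.id,
                    motif_id=pattern.motif_id,
                    start=start,
                    end=start + m,
                    matched=seq[start : start + m],
                )
            )
    return hits


def _nonoverlapping_count(hits: list[MotifHit]) -> int:
    """Leftmost-greedy selection of non-overlapping hits."""
    count = 0
    cursor = -1
    for hit in sorted(hits, key=lambda h: h.start):
        if hit.start >= cursor:
            count += 1
            cursor = hit.end
    return count


def classify(
    protein: ProteinRecord,
    motif_library: list[MotifPattern] | None = None,
    rules: ClassificationRules = ClassificationRules(),
) -> FamilyCall:
    """Assign a candidate family from motif co-occurrence.

    HAK if >= rules.hak_min of the five HAK motifs match; HKT if both HKT
    motifs match; CHANNEL if the pore motif (motif 1) matches.  When
    classes conflict, precedence is HAK > HKT > CHANNEL.  Evidence lists
    hits from all motifs regardless of the final label.
    """
    library = motif_library if motif_library is not None else load_motif_library()
    all_hits: list[MotifHit] = []
    hits_by_motif: dict[int, list[MotifHit]] = {}
    for pattern in library:
        hits = scan(protein, pattern)
        if hits:
            hits_by_motif.setdefault(pattern.motif_id, []).extend(hits)
            all_hits.extend(hits)
    matched = frozenset(hits_by_motif)

    hak_ids = {p.motif_id for p in library if p.family_class == "HAK"}
    hkt_ids = sorted(p.motif_id for p in library if p.family_class == "HKT")
    pore_id = min(
        (p.motif_id for p in library if p.family_class == "CHANNEL"), default=None
    )

    is_hak = len(matched & hak_ids) >= rules.hak_min
    if rules.hkt_require_both:
        is_hkt = bool(hkt_ids) and all(m in matched for m in hkt_ids)
    else:
        is_hkt = bool(matched & set(hkt_ids))
    pore_hits = hits_by_motif.get(pore_id, [])
    pore_count = _nonoverlapping_count(pore_hits)
    is_channel = pore_count >= rules.channel_min_pore

    if is_hak:
        family = "HAK"
    elif is_hkt:
        family = "HKT"
    elif is_channel:
        family = "CHANNEL"
    else:
        family = "UNCLASSIFIED"

    if family == "CHANNEL":
        channel_pores = pore_count
        if channel_pores == 1:
            subtype = "SINGLE_PORE"
        elif channel_pores == 2:
            subtype = "TANDEM_PORE"
        else:
            subtype = "MULTI"
    else:
        channel_pores = 0
        subtype = "NA"

    return FamilyCall(
        protein_id=protein.id,
        family=family,
        channel_pore_count=channel_pores,
        channel_subtype=subtype,
        evidence=tuple(sorted(all_hits, key=lambda h: (h.motif_id, h.start))),
        motif_ids_matched=matched,
    )
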
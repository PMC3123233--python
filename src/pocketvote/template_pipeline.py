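"""Template library construction.

Reads a plain-text template list (one PDB ID or file path per line),
restricts each template's HETATM groups to a configurable list of
biologically relevant ligand codes, enforces 70% pairwise sequence
non-redundancy with a greedy scan in input order, and caps the library at
40 templates.  Sequence identity is computed from a global alignment
(match +1, mismatch 0, linear gap -1) and normalised by the shorter
sequence length, the convention used by fragment-tolerant redundancy
screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio.Align import PairwiseAligner

from .errors import InputError, TemplateError
from .structure_io import Ligand, StructureModel, parse_pdb

log = logging.getLogger(__name__)

# Default biologically relevant ligand codes: common catalytic/structural
# metals, nucleotides and analogues, cofactors, sugars and small anions.
# The clustering and voting algorithms are parameterised by this list; a
# user-supplied list (one code per line) overrides it.
DEFAULT_RELEVANT_CODES = frozenset({
    # metals / ions
    "ZN", "MG", "MN", "FE", "FE2", "CA", "NI", "CU", "CO", "NA", "K",
    "CL", "CD", "MO", "W",
    # nucleotides and analogues
    "ATP", "ADP", "AMP", "GTP", "GDP", "GMP", "GNP", "ANP", "ACP", "ADN",
    "STU", "UMP", "UDP", "UTP", "CMP", "CDP", "CTP", "TMP", "TDP", "TTP",
    "NAD", "NAP", "NDP", "FAD", "FMN",
    # cofactors and prosthetic groups
    "HEM", "HEC", "SAM", "SAH", "PLP", "COA", "ACO", "TPP", "THF", "BTN",
    "B12", "CLA", "BCL", "RET",
    # sugars, phosphates, small organics
    "GLC", "GAL", "MAN", "FRU", "SUC", "TRE", "MAL", "NAG", "NDG", "BMA",
    "PO4", "SO4", "PYR", "CIT", "AKG", "OXL", "MLI", "FUM",
})


@dataclass(frozen=True)
class RelevantLigandList:
    codes: frozenset[str] = DEFAULT_RELEVANT_CODES

    def __post_init__(self) -> None:
        codes = frozenset(c.upper() for c in self.codes) - {"HOH", "WAT", "DOD"}
        if not codes:
            raise InputError("relevant-ligand list is empty")
        object.__setattr__(self, "codes", codes)

    def __contains__(self, code: str) -> bool:
        return code.upper() in self.codes

    @classmethod
    def from_file(cls, path: str | Path) -> "RelevantLigandList":
        codes = set()
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                codes.add(line.upper())
        return cls(codes=frozenset(codes))


@dataclass
class TemplateEntry:
    template_id: str
    structure: StructureModel
    ligands: list[Ligand] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return self.structure.sequence


def load_template_list(
    path: str | Path, structure_dir: str | Path | None = None
) -> list[TemplateEntry]:
    """Resolve a one-ID-per-line template list into parsed entries.

    IDs resolve as ``<structure_dir>/<id>.pdb``; a line that is an existing
    path is used directly.  Missing files are skipped with a warning,
    duplicates keep the first occurrence, and input order is preserved.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"template list not found: {path}")
    structure_dir = Path(structure_dir) if structure_dir is not None else path.parent
    entries: list[TemplateEntry] = []
    seen: set[str] = set()
    for raw in path.read_text().splitlines():
        token = raw.split("#", 1)[0].strip()
        if not token:
            continue
        # an explicit path wins; otherwise treat the token as an ID
        candidate = Path(token)
        if not candidate.is_file():
            candidate = structure_dir / f"{token}.pdb"
        tid = candidate.stem
        if tid in seen:
            continue
        if not candidate.is_file():
            log.warning("template %s: file %s not found, skipping", token, candidate)
            continue
        seen.add(tid)
        structure, ligands = parse_pdb(candidate, target_id=tid)
        entries.append(TemplateEntry(template_id=tid, structure=structure, ligands=ligands))
    if not entries:
        raise TemplateError(f"no templates could be resolved from {path}")
    return entries


def filter_relevant_ligands(
    entry: TemplateEntry, allowed: RelevantLigandList
) -> TemplateEntry:
    """Restrict a template's ligands to the biologically relevant codes.

    An entry is retained even if no ligands remain; it is only dropped
    later, at the clustering stage, where an empty pool is reported.
    """
    kept = [lig for lig in entry.ligands if lig.het_code in allowed]
    if len(kept) < len(entry.ligands):
        log.info(
            "template %s: %d of %d ligand groups kept after relevance filter",
            entry.template_id, len(kept), len(entry.ligands),
        )
    return replace(entry, ligands=kept)


def _make_aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=0.0,
        open_gap_score=-1.0,
        extend_gap_score=-1.0,
    )


def global_alignment_pairs(a: str, b: str) -> list[tuple[int, int]]:
    """Aligned index pairs (i in a, j in b) from the global alignment."""
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    aln = _make_aligner().align(a, b)[0]
    pairs: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        pairs.extend(zip(range(s1, e1), range(s2, e2)))
    return pairs


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: identical pairs / min(len(a), len(b))."""
    pairs = global_alignment_pairs(a, b)
    identical = sum(1 for i, j in pairs if a[i] == b[j])
    return identical / min(len(a), len(b))


def filter_redundancy(
    entries: list[TemplateEntry], threshold: float = 0.70, cap: int = 40
) -> list[TemplateEntry]:
    """Greedy non-redundancy filter followed by a hard size cap.

    Scanning in input order, an entry is kept iff its sequence identity to
    every already-kept entry is below ``threshold``; the kept list is then
    truncated to the first ``cap`` entries.  Deterministic.
    """
    kept: list[TemplateEntry] = []
    for entry in entries:
        if len(kept) >= cap:
            break
        if all(
            sequence_identity(entry.sequence, other.sequence) < threshold
            for other in kept
        ):
            kept.append(entry)
        else:
            log.info("template %s dropped as redundant", entry.template_id)
    return kept[:cap]
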
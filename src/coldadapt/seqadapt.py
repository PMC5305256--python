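"""Composition comparison and substitution classification on
temperature-labeled multiple sequence alignments.

Two homologs (one cold-adapted, one mesophilic) are compared column by
column; each substitution between them is classified as a cold-adaptation
*candidate* (both temperature groups conserve different residues and each
target matches its own group), *drift* (the mesophilic group is itself
heterogeneous, or both groups conserve the same residue), or
*indeterminate*.  Group evidence excludes the two targets themselves: a
substitution is only a candidate when it is echoed by *other* organisms of
the same thermal class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "LabeledAlignment",
    "CompositionDelta",
    "SubstitutionRecord",
    "composition_delta",
    "substitution_sites",
    "classify_substitutions",
    "pairwise_identity",
    "read_labeled_alignment",
    "AA_CLASSES",
]

VALID_LABELS = {"psychrophilic", "psychrotolerant", "mesophilic"}
GAP_CHARS = {"-", "."}
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: residue class table used for grouped composition summaries (classes may
#: overlap: aromatics are also counted among hydrophobics where applicable)
AA_CLASSES = {
    "charged": set("DEKRH"),
    "polar": set("STNQCY"),
    "hydrophobic": set("AVLIMFWP"),
    "aromatic": set("FYWH"),
}

#: default residue-similarity groups for the optional similarity-class mode
SIMILARITY_GROUPS = [set("VIL"), set("ST"), set("DE"), set("KR"), set("FYW"),
                     set("NQ")]


@dataclass
class LabeledAlignment:
    """Aligned sequences plus per-sequence temperature labels and the two
    designated comparison targets (``target_a`` cold, ``target_b`` warm)."""

    sequences: list[str]
    ids: list[str]
    labels: dict[str, str]
    target_a: str
    target_b: str

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.ids):
            raise ValueError("one id per sequence required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
        for sid in self.ids:
            if sid not in self.labels:
                raise ValueError(f"sequence {sid!r} has no temperature label")
            if self.labels[sid] not in VALID_LABELS:
                raise ValueError(
                    f"label {self.labels[sid]!r} for {sid!r} not in {sorted(VALID_LABELS)}"
                )
        for t in (self.target_a, self.target_b):
            if t not in self.ids:
                raise ValueError(f"target {t!r} not among sequence ids")
        if self.labels[self.target_a] != "psychrophilic":
            raise ValueError("target_a must be labeled psychrophilic")
        if self.labels[self.target_b] != "mesophilic":
            raise ValueError("target_b must be labeled mesophilic")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def sequence(self, sid: str) -> str:
        return self.sequences[self.ids.index(sid)]

    def group_ids(self, pool_cold: bool = True) -> tuple[list[str], list[str]]:
        """(cold, mesophilic) id lists; psychrotolerant pooled with
        psychrophilic by default."""
        cold_labels = {"psychrophilic", "psychrotolerant"} if pool_cold \
            else {"psychrophilic"}
        cold = [s for s in self.ids if self.labels[s] in cold_labels]
        meso = [s for s in self.ids if self.labels[s] == "mesophilic"]
        return cold, meso

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")

    def write_labels_tsv(self, path) -> None:
        pd.DataFrame({"id": self.ids,
                      "label": [self.labels[s] for s in self.ids]}
                     ).to_csv(path, sep="\t", index=False)


def read_labeled_alignment(alignment_path, labels_path, target_a: str,
                           target_b: str, format: str = "fasta") -> LabeledAlignment:
    """Read an alignment (FASTA or Clustal, via Bio.AlignIO) plus a two-column
    ``id<TAB>label`` TSV into a :class:`LabeledAlignment`."""
    from Bio import AlignIO

    aln = AlignIO.read(str(alignment_path), "clustal" if format == "clustal" else "fasta")
    ids = [rec.id for rec in aln]
    sequences = [str(rec.seq).upper() for rec in aln]
    table = pd.read_csv(labels_path, sep="\t")
    if not {"id", "label"} <= set(table.columns):
        raise ValueError("labels TSV needs 'id' and 'label' columns")
    labels = dict(zip(table["id"].astype(str), table["label"].astype(str)))
    return LabeledAlignment(sequences=sequences, ids=ids, labels=labels,
                            target_a=target_a, target_b=target_b)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

@dataclass
class CompositionDelta:
    counts_a: dict
    counts_b: dict
    delta: dict
    class_delta: dict
    target_a: str
    target_b: str

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(set(self.counts_a) | set(self.counts_b))
        return pd.DataFrame({
            "residue": rows,
            self.target_a: [self.counts_a.get(r, 0) for r in rows],
            self.target_b: [self.counts_b.get(r, 0) for r in rows],
            "delta": [self.delta.get(r, 0) for r in rows],
        })


def _ungapped(seq: str) -> str:
    return "".join(c for c in seq if c not in GAP_CHARS)


def composition_delta(alignment: LabeledAlignment) -> CompositionDelta:
    """Per-residue-type counts for the two targets and their signed
    difference (target_a − target_b), plus grouped class summaries."""
    seq_a = _ungapped(alignment.sequence(alignment.target_a))
    seq_b = _ungapped(alignment.sequence(alignment.target_b))
    bad = (set(seq_a) | set(seq_b)) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-standard residue letters: {sorted(bad)}")
    ca, cb = Counter(seq_a), Counter(seq_b)
    delta = {r: ca.get(r, 0) - cb.get(r, 0) for r in sorted(set(ca) | set(cb))}
    class_delta = {
        cls: sum(ca.get(r, 0) for r in members) - sum(cb.get(r, 0) for r in members)
        for cls, members in AA_CLASSES.items()
    }
    return CompositionDelta(counts_a=dict(ca), counts_b=dict(cb), delta=delta,
                            class_delta=class_delta,
                            target_a=alignment.target_a,
                            target_b=alignment.target_b)


# ---------------------------------------------------------------------------
# Substitution sites and classification
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionRecord:
    """One alignment column where the two targets differ."""

    column: int
    label_a: str
    label_b: str
    reference_position: str
    kind: str = "substitution"      # substitution | insertion_a | insertion_b
    verdict: str | None = None      # candidate | drift | indeterminate
    evidence: dict = field(default_factory=dict)


def substitution_sites(alignment: LabeledAlignment,
                       numbering_map: dict[int, str] | None = None) -> list[SubstitutionRecord]:
    """Every column where the targets differ.

    Columns with residues in both targets yield substitution records; columns
    gapped in exactly one target yield insertion/deletion records (reported,
    never dropped).  ``reference_position`` is taken from ``numbering_map``
    (keyed by target_a ungapped position) when given, else from target_a's
    ungapped position (1-based).
    """
    seq_a = alignment.sequence(alignment.target_a)
    seq_b = alignment.sequence(alignment.target_b)
    records = []
    pos_a = 0
    for col, (a, b) in enumerate(zip(seq_a, seq_b)):
        gap_a = a in GAP_CHARS
        gap_b = b in GAP_CHARS
        if not gap_a:
            pos_a += 1
        if gap_a and gap_b:
            continue
        ref = (numbering_map or {}).get(pos_a, str(pos_a)) if not gap_a else "-"
        if a == b:
            continue
        if gap_a:
            records.append(SubstitutionRecord(col, "-", b, ref, kind="insertion_b"))
        elif gap_b:
            records.append(SubstitutionRecord(col, a, "-", ref, kind="insertion_a"))
        else:
            records.append(SubstitutionRecord(col, a, b, ref))
    return records


def _canon(residue: str, groups) -> str:
    if groups:
        for g in groups:
            if residue in g:
                return min(g)
    return residue


def _column_consensus(alignment: LabeledAlignment, ids: list[str], col: int,
                      groups) -> tuple[str | None, float, int]:
    residues = [
        _canon(alignment.sequence(sid)[col], groups)
        for sid in ids if alignment.sequence(sid)[col] not in GAP_CHARS
    ]
    if not residues:
        return None, 0.0, 0
    counts = Counter(residues)
    mode, n = counts.most_common(1)[0]
    return mode, n / len(residues), len(residues)


def classify_substitutions(records: list[SubstitutionRecord],
                           alignment: LabeledAlignment,
                           conservation_cutoff: float = 0.8,
                           pool_cold: bool = True,
                           use_similarity_groups: bool = False) -> list[SubstitutionRecord]:
    """Attach a candidate/drift/indeterminate verdict to each substitution.

    Consensus is computed over each temperature group *excluding* the two
    targets.  ``candidate``: both groups conserved (modal frequency >=
    cutoff) on different residues, with each target matching its own
    group's mode.  ``drift``: the mesophilic group is heterogeneous, or both
    groups share the same modal residue.  Anything else (including columns
    where a group has no non-target evidence) is ``indeterminate``.
    With ``use_similarity_groups``, residues are compared through a
    substitution-group table (V/I/L, S/T, ...) instead of exact identity.
    """
    if not 0.0 < conservation_cutoff <= 1.0:
        raise ValueError("conservation_cutoff must be in (0, 1]")
    cold_ids, meso_ids = alignment.group_ids(pool_cold=pool_cold)
    if not cold_ids or not meso_ids:
        raise ValueError("both temperature groups must contain sequences")
    cold_others = [s for s in cold_ids if s != alignment.target_a]
    meso_others = [s for s in meso_ids if s != alignment.target_b]
    groups = SIMILARITY_GROUPS if use_similarity_groups else None

    out = []
    for rec in records:
        if rec.kind != "substitution":
            out.append(rec)
            continue
        cold_mode, cold_freq, cold_n = _column_consensus(
            alignment, cold_others, rec.column, groups)
        meso_mode, meso_freq, meso_n = _column_consensus(
            alignment, meso_others, rec.column, groups)
        evidence = {
            "cold_mode": cold_mode, "cold_freq": round(cold_freq, 4),
            "cold_n": cold_n,
            "meso_mode": meso_mode, "meso_freq": round(meso_freq, 4),
            "meso_n": meso_n,
        }
        a = _canon(rec.label_a, groups)
        b = _canon(rec.label_b, groups)
        if cold_n == 0 or meso_n == 0:
            verdict = "indeterminate"
        elif cold_mode == meso_mode:
            verdict = "drift"
        elif meso_freq < conservation_cutoff:
            verdict = "drift"
        elif (cold_freq >= conservation_cutoff and a == cold_mode
              and b == meso_mode):
            verdict = "candidate"
        else:
            verdict = "indeterminate"
        out.append(SubstitutionRecord(rec.column, rec.label_a, rec.label_b,
                                      rec.reference_position, rec.kind,
                                      verdict, evidence))
    return out


def records_to_frame(records: list[SubstitutionRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "column": r.column, "ref_position": r.reference_position,
        "a": r.label_a, "b": r.label_b, "kind": r.kind,
        "verdict": r.verdict,
        **{f"evidence_{k}": v for k, v in (r.evidence or {}).items()},
    } for r in records])


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over columns where both sequences have a residue."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    comparable = ident = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        comparable += 1
        if a == b:
            ident += 1
    if comparable == 0:
        raise ValueError("no comparable (mutually ungapped) positions")
    return 100.0 * ident / comparable
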
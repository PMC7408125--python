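"""Diagnostic tag-fragment screening and group classification.

Three diagnostic ("tag") fragment ions partition the bagremycin-related
chemistry into groups: m/z 121.06 for the classical bagremycins (the
p-vinylphenol-derived moiety), m/z 255.04 for the sulfur-bearing
bagremycins (N-acetylcysteine conjugates) and m/z 178.05 for the
bagrelactones, with 176.0706 as an unsaturated alternative of the group-3
tag.  The printed m/z values are authoritative for matching; the published
formula of the group-1 tag (C8H8O+) computes to 120.06 and is recorded as a
note only.

A tag may also leave as a neutral loss: the diagnostic moiety departs
uncharged, observed as a fragment at precursor minus the tag's neutral
mass (tag m/z minus one proton) instead of the charged tag itself.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .formula import PROTON_MASS
from .spectra import Spectrum

__all__ = ["TagDefinition", "TagEvidence", "GroupCall", "default_tag_set",
           "read_tag_set", "screen_tags", "classify_node"]


@dataclass(frozen=True)
class TagDefinition:
    group: str
    tag_mz: float
    formula_note: str = ""
    alt_mz: float | None = None
    allow_neutral_loss: bool = False

    def __post_init__(self) -> None:
        if self.tag_mz <= 0:
            raise ValueError("tag m/z must be positive")

    @property
    def neutral_mass(self) -> float:
        """Mass of the uncharged moiety for neutral-loss matching."""
        return self.tag_mz - PROTON_MASS


@dataclass(frozen=True)
class TagEvidence:
    group: str
    matched_mz: float   # the fragment m/z that produced the hit
    target_mz: float    # the tag (or alt) value it matched
    mode: str           # "direct", "alt" or "neutral-loss"


@dataclass(frozen=True)
class GroupCall:
    node_id: str
    group: str          # "1", "2", "3" or "ND"
    evidence: tuple[TagEvidence, ...]
    ambiguous: bool = False   # multi-tag evidence or a tie between groups


def default_tag_set() -> list[TagDefinition]:
    """The three diagnostic bagremycin-group tags."""
    return [
        TagDefinition("1", 121.06, "printed as C8H8O+ (computes to C8H9O+)",
                      allow_neutral_loss=True),
        TagDefinition("2", 255.04, "C10H11N2O4S+"),
        TagDefinition("3", 178.05, "C9H8NO3+", alt_mz=176.0706,
                      allow_neutral_loss=True),
    ]


def read_tag_set(path: str | Path) -> list[TagDefinition]:
    """Load tag definitions from TSV (columns: group, mz, alt_mz, nl, note)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"group", "mz"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: tag table needs columns {sorted(required)}")
    tags = []
    for _, row in df.iterrows():
        alt = row.get("alt_mz", "")
        tags.append(
            TagDefinition(
                group=str(row["group"]),
                tag_mz=float(row["mz"]),
                formula_note=str(row.get("note", "") or ""),
                alt_mz=float(alt) if alt not in ("", None) and not pd.isna(alt) else None,
                allow_neutral_loss=str(row.get("nl", "0")) in ("1", "true", "True"),
            )
        )
    groups = [t.group for t in tags]
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group labels in tag set")
    return tags


def screen_tags(
    s: Spectrum,
    tags: Sequence[TagDefinition] | None = None,
    tol_da: float = 0.01,
) -> list[TagEvidence]:
    """Search one spectrum for diagnostic tag fragments.

    Direct hits match a fragment against the tag (or alternative) m/z within
    ``tol_da``; neutral-loss hits match precursor-minus-fragment against the
    tag's neutral mass, only for tags that allow it.
    """
    if s.n_peaks == 0:
        raise ValueError("cannot screen an empty spectrum")
    if tags is None:
        tags = default_tag_set()
    evidence: list[TagEvidence] = []
    for tag in tags:
        targets = [(tag.tag_mz, "direct")]
        if tag.alt_mz is not None:
            targets.append((tag.alt_mz, "alt"))
        hit = None
        for target, mode in targets:
            for mz in s.mz:
                if abs(mz - target) <= tol_da:
                    hit = TagEvidence(tag.group, float(mz), target, mode)
                    break
            if hit:
                break
        if hit is None and tag.allow_neutral_loss:
            for mz in s.mz:
                if abs((s.precursor_mz - mz) - tag.neutral_mass) <= tol_da:
                    hit = TagEvidence(tag.group, float(mz), tag.tag_mz, "neutral-loss")
                    break
        if hit:
            evidence.append(hit)
    return evidence


def classify_node(
    node_id: str,
    member_evidence: Iterable[Sequence[TagEvidence]],
) -> GroupCall:
    """Assign a group to a consensus node from its members' tag evidence.

    Each member votes for the single group its evidence supports; a member
    whose evidence spans several groups makes the node ambiguous (ND), as
    does a tie between groups across members.  Nodes without any evidence
    are ND without the ambiguity flag.

    Directly observed tag fragments outrank neutral-loss inferences: a
    neutral-loss hit only counts for a member without any direct (or
    alternative-mass) hit.  The precedence matters in practice — a
    precursor sitting one tag-mass above another tag produces a spurious
    neutral-loss coincidence that must not override the observed fragment.
    """
    member_evidence = [tuple(ev) for ev in member_evidence]
    if not member_evidence:
        raise ValueError("classify_node needs at least one member spectrum")
    all_evidence = tuple(e for ev in member_evidence for e in ev)
    votes: Counter[str] = Counter()
    multi_tag = False
    for ev in member_evidence:
        direct = {e.group for e in ev if e.mode in ("direct", "alt")}
        groups = direct if direct else {e.group for e in ev}
        if len(groups) == 1:
            votes[groups.pop()] += 1
        elif len(groups) > 1:
            multi_tag = True
    if multi_tag:
        return GroupCall(node_id, "ND", all_evidence, ambiguous=True)
    if not votes:
        return GroupCall(node_id, "ND", all_evidence, ambiguous=False)
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return GroupCall(node_id, "ND", all_evidence, ambiguous=True)
    return GroupCall(node_id, ranked[0][0], all_evidence, ambiguous=False)
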
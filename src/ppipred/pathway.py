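"""Co-pathway similarity from a protein -> pathway membership table.

The table is a generic stand-in for KEGG gene-pathway links: two tab
separated columns (protein id, pathway id), one membership per line.
Similarity is the Jaccard index of the two pathway sets; a pair in which
neither protein belongs to any pathway is treated as missing (the measure
cannot work), while exactly one empty side scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MalformedTableError
from .missing import MISSING


@dataclass
class PathwayMembership:
    """Protein id -> set of pathway ids (opaque strings)."""

    pathways: dict[str, set[str]] = field(default_factory=dict)

    def get(self, protein: str) -> set[str]:
        return self.pathways.get(protein, set())


def parse_pathway_table(path) -> PathwayMembership:
    """Read a two-column TSV of (protein_id, pathway_id) memberships.

    Duplicate lines collapse; an empty file yields an empty membership.
    Raises :class:`MalformedTableError` naming the offending line.
    """
    pathways: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(fields):
                raise MalformedTableError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            protein, pathway = fields
            pathways.setdefault(protein, set()).add(pathway)
    return PathwayMembership(pathways)


def kegg_sim(pm: PathwayMembership, i: str, j: str) -> float:
    """Jaccard index of the pathway sets of proteins ``i`` and ``j``.

    Returns MISSING when both sets are empty, 0.0 when exactly one is.
    """
    pi, pj = pm.get(i), pm.get(j)
    if not pi and not pj:
        return MISSING
    if not pi or not pj:
        return 0.0
    return len(pi & pj) / len(pi | pj)
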
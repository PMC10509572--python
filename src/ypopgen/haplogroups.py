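"""ISOGG-style Y-haplogroup nomenclature: parsing, collapsing, assignment.

A haplogroup name is a trunk capital letter followed by alternating
digit/letter refinements ("C2a1a3"), optionally a trailing "*" marking a
paraphyletic residue, and optionally a "-SNP" suffix naming the defining SNP
("C2a1a3-M504").  Because the nomenclature encodes topology, a tree can be
reconstructed from a flat list of (name, defining SNP) pairs: each node's
parent is its longest proper nomenclature prefix present in the list, falling
back to the trunk letter and then to a synthetic root.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

ROOT_NAME = "Y"  # synthetic root above the trunk letters

SNPState = Literal["A", "D", "U"]  # ancestral / derived / untyped

_TOKEN_RE = re.compile(r"\d+|[a-z]+")


class HaplogroupParseError(ValueError):
    pass


class HaplogroupConflictError(ValueError):
    """Derived SNPs on incompatible lineages."""

    def __init__(self, snps: list[str]):
        super().__init__(f"derived SNPs off the assignment path: {', '.join(sorted(snps))}")
        self.snps = snps


@dataclass(frozen=True)
class HaplogroupName:
    trunk: str
    path: tuple[str, ...] = ()
    snp_label: str | None = None
    star: bool = False

    def render(self) -> str:
        s = self.trunk + "".join(self.path)
        if self.star:
            s += "*"
        if self.snp_label:
            s += f"-{self.snp_label}"
        return s

    def __str__(self) -> str:
        return self.render()

    @property
    def depth(self) -> int:
        """Number of refinements below the trunk."""
        return len(self.path)

    def bare(self) -> str:
        """Name without star or SNP suffix."""
        return self.trunk + "".join(self.path)


def parse_haplogroup_name(s: str) -> HaplogroupName:
    """Parse a nomenclature string such as "C2a1a1b1-F1756" or "C*-M130"."""
    s = s.strip()
    if not s:
        raise HaplogroupParseError("empty haplogroup name")
    snp_label: str | None = None
    if "-" in s:
        s, snp_label = s.split("-", 1)
        snp_label = snp_label.strip() or None
    star = s.endswith("*")
    if star:
        s = s[:-1]
    if not s or not s[0].isupper() or not s[0].isalpha():
        raise HaplogroupParseError(f"trunk must be a capital letter in {s!r}")
    trunk, rest = s[0], s[1:]
    tokens = _TOKEN_RE.findall(rest)
    if "".join(tokens) != rest:
        raise HaplogroupParseError(f"invalid characters in haplogroup path {rest!r}")
    for i, tok in enumerate(tokens):
        expect_digit = i % 2 == 0
        if expect_digit != tok.isdigit():
            raise HaplogroupParseError(
                f"path must alternate digit/letter starting with a digit: {rest!r}"
            )
    return HaplogroupName(trunk=trunk, path=tuple(tokens), snp_label=snp_label, star=star)


def collapse_to_level(name: HaplogroupName | str, level: int) -> HaplogroupName:
    """Truncate a name to ``level`` refinements below the trunk.

    Level 0 keeps the trunk letter only.  Collapsing strips the SNP suffix
    and star flag whenever truncation occurs (they describe the terminal
    call, not the coarser clade); a name already at or above the level is
    returned unchanged.  Idempotent.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if isinstance(name, str):
        name = parse_haplogroup_name(name)
    if name.depth <= level:
        return name
    return HaplogroupName(trunk=name.trunk, path=name.path[:level])


@dataclass
class HaplogroupTree:
    """Rooted nomenclature tree: name -> (parent name, defining SNP)."""

    nodes: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if ROOT_NAME not in self.nodes:
            self.nodes[ROOT_NAME] = ("", None)
        snps = [snp for _, (_, snp) in self.nodes.items() if snp]
        if len(snps) != len(set(snps)):
            raise ValueError("defining SNPs must be unique across the tree")
        for name in self.nodes:
            if name != ROOT_NAME:
                self._check_acyclic(name)

    def _check_acyclic(self, name: str) -> None:
        seen = set()
        while name != ROOT_NAME:
            if name in seen:
                raise ValueError(f"cycle through {name!r}")
            seen.add(name)
            name = self.parent(name)

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str | None]]) -> "HaplogroupTree":
        """Build a tree from (name, defining SNP) with parents from nomenclature."""
        bare_names = {}
        for raw, snp in pairs:
            hn = parse_haplogroup_name(raw)
            bare_names[hn.bare()] = snp
        nodes: dict[str, tuple[str, str | None]] = {ROOT_NAME: ("", None)}
        for bare in sorted(bare_names, key=len):
            hn = parse_haplogroup_name(bare)
            parent = ROOT_NAME
            for k in range(hn.depth - 1, -1, -1):
                cand = hn.trunk + "".join(hn.path[:k])
                if cand in bare_names and cand != bare:
                    parent = cand
                    break
            nodes[bare] = (parent, bare_names[bare])
        return cls(nodes=nodes)

    @classmethod
    def read(cls, path: str | Path) -> "HaplogroupTree":
        df = pd.read_csv(path, sep="\t")
        if "haplogroup" not in df.columns or "defining_snp" not in df.columns:
            raise ValueError("tree file needs columns: haplogroup, defining_snp")
        pairs = [
            (str(r.haplogroup), None if pd.isna(r.defining_snp) else str(r.defining_snp))
            for r in df.itertuples()
        ]
        return cls.from_pairs(pairs)

    def write(self, path: str | Path) -> None:
        rows = [
            {"haplogroup": name, "defining_snp": snp or ""}
            for name, (_, snp) in sorted(self.nodes.items())
            if name != ROOT_NAME
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def parent(self, name: str) -> str:
        return self.nodes[name][0]

    def defining_snp(self, name: str) -> str | None:
        return self.nodes[name][1]

    def children(self, name: str) -> list[str]:
        return sorted(n for n, (p, _) in self.nodes.items() if p == name and n != ROOT_NAME)

    def ancestors(self, name: str) -> list[str]:
        """Path root -> name, exclusive of the root, inclusive of name."""
        chain = []
        while name != ROOT_NAME:
            chain.append(name)
            name = self.parent(name)
        return chain[::-1]

    def snp_to_node(self) -> dict[str, str]:
        return {snp: n for n, (_, snp) in self.nodes.items() if snp}

    def members(self, clade: str) -> list[str]:
        """All nodes in the subtree rooted at ``clade`` (inclusive)."""
        out, stack = [], [clade]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children(n))
        return sorted(out)


def assign_haplogroup(
    snp_states: Mapping[str, str], tree: HaplogroupTree
) -> HaplogroupName:
    """Assign the deepest haplogroup consistent with SNP derived states.

    The result is the deepest node whose defining SNP is derived and whose
    every *typed* ancestor-defining SNP is also derived; untyped SNPs are
    unknown, never ancestral.  With no derived SNP the synthetic root is
    returned.  A derived SNP off the root-to-result path raises
    :class:`HaplogroupConflictError`.  When all typed daughter SNPs of the
    result are ancestral the paraphyletic star flag is set.
    """
    snp_map = tree.snp_to_node()
    derived_nodes = [snp_map[s] for s, st in snp_states.items() if st == "D" and s in snp_map]
    if not derived_nodes:
        return HaplogroupName(trunk=ROOT_NAME)

    def consistent(node: str) -> bool:
        for anc in tree.ancestors(node):
            snp = tree.defining_snp(anc)
            if snp is not None and snp_states.get(snp, "U") == "A":
                return False
        return True

    candidates = [n for n in derived_nodes if consistent(n)]
    if not candidates:
        raise HaplogroupConflictError(
            [tree.defining_snp(n) or n for n in derived_nodes]
        )
    best = max(candidates, key=lambda n: (len(tree.ancestors(n)), n))
    on_path = set(tree.ancestors(best))
    off_path = [n for n in derived_nodes if n not in on_path]
    if off_path:
        raise HaplogroupConflictError([tree.defining_snp(n) or n for n in off_path])

    daughters = tree.children(best)
    daughter_snps = [tree.defining_snp(d) for d in daughters]
    typed = [s for s in daughter_snps if s is not None and snp_states.get(s, "U") != "U"]
    star = bool(typed) and all(snp_states.get(s) == "A" for s in typed if s is not None)
    hn = parse_haplogroup_name(best) if best != ROOT_NAME else HaplogroupName(trunk=ROOT_NAME)
    return replace(hn, star=star, snp_label=tree.defining_snp(best))


# A compact default nomenclature tree covering the major East Asian clades
# used by the simulator and examples.  SNP labels follow public ISOGG usage.
DEFAULT_TREE_PAIRS: tuple[tuple[str, str], ...] = (
    ("C", "M130"), ("C2", "M217"), ("C2a", "L1373"), ("C2b", "F1067"),
    ("C2a1a2", "M48"), ("C2a1a3", "M504"),
    ("D", "M174"), ("D1a1", "M15"),
    ("E", "M96"),
    ("F", "M89"),
    ("G", "M201"),
    ("H", "L901"),
    ("I", "M170"),
    ("J", "M304"), ("J2", "M172"),
    ("L", "M20"),
    ("N", "M231"), ("N1a", "F1206"), ("N1b", "F2930"),
    ("O", "M175"), ("O1", "F265"), ("O2", "M122"),
    ("O1a", "M119"), ("O1b", "M268"),
    ("O2a1", "L467"), ("O2a2", "P201"),
    ("P", "P295"),
    ("Q", "M242"),
    ("R", "M207"), ("R1", "M173"), ("R1a", "M420"), ("R2", "M479"),
    ("T", "M184"),
)


def default_tree() -> HaplogroupTree:
    return HaplogroupTree.from_pairs(list(DEFAULT_TREE_PAIRS))
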
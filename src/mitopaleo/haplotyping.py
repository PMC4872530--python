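"""Haplogroup classification and archaic screening of a mitogenome.

A haplogroup is a named clade of the mitochondrial phylogeny defined by a
set of diagnostic substitutions.  This module loads a PhyloTree-style
diagnostic-site table (a stylised subset covering the lineage path
N -> R -> U -> U6 and its derived branches ships with the package),
classifies a variant list into the deepest clade whose own diagnostics are
all present, screens the haplotype against archaic (Neandertal-type)
diagnostic positions, and identifies private mutations absent from a
reference panel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .contamination import ReferencePanel
from .reference import load_reference
from .variants import MtVariant, validate_against_reference

ROOT_NAME = "REF"


@dataclass
class HaplogroupDefinition:
    """One named clade: its parent and its diagnostic substitutions."""

    name: str
    parent: str | None
    diagnostics: tuple[MtVariant, ...]


@dataclass
class HaplogroupTree:
    """Acyclic clade hierarchy rooted at the reference node."""

    nodes: dict[str, HaplogroupDefinition]

    def __post_init__(self) -> None:
        if ROOT_NAME not in self.nodes:
            self.nodes[ROOT_NAME] = HaplogroupDefinition(ROOT_NAME, None, ())
        for name, node in self.nodes.items():
            if name == ROOT_NAME:
                continue
            if node.parent not in self.nodes:
                raise ValueError(f"clade {name} has unknown parent {node.parent}")
            if not node.diagnostics:
                raise ValueError(f"non-root clade {name} has no diagnostics")
        # cycle check: every node must reach the root
        for name in self.nodes:
            seen = set()
            cur = name
            while cur != ROOT_NAME:
                if cur in seen:
                    raise ValueError(f"cycle in parent links at {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def children(self, name: str) -> list[str]:
        return [n for n, d in self.nodes.items() if d.parent == name]

    def path_to_root(self, name: str) -> list[str]:
        """Clade names from the root (exclusive) down to ``name``."""
        path = []
        cur = name
        while cur != ROOT_NAME:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path[::-1]

    def depth(self, name: str) -> int:
        return len(self.path_to_root(name))


def load_haplogroup_tree(path=None) -> HaplogroupTree:
    """Load diagnostic-site definitions from a TSV (packaged file by default).

    Columns: haplogroup, parent, position, ref, alt; one row per diagnostic
    site.  Lines starting with '#' are comments.
    """
    if path is None:
        source = resources.files("mitopaleo.data").joinpath("haplogroups.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = _read_tsv(text)
    nodes: dict[str, HaplogroupDefinition] = {}
    diag: dict[str, list[MtVariant]] = {}
    parents: dict[str, str] = {}
    for row in rows:
        name = row["haplogroup"]
        parents.setdefault(name, row["parent"])
        if parents[name] != row["parent"]:
            raise ValueError(f"clade {name} listed with two parents")
        diag.setdefault(name, []).append(
            MtVariant(position=int(row["position"]), ref=row["ref"], alt=row["alt"])
        )
    for name, variants in diag.items():
        validate_against_reference(variants)
        nodes[name] = HaplogroupDefinition(
            name=name, parent=parents[name], diagnostics=tuple(sorted(variants))
        )
    return HaplogroupTree(nodes=nodes)


def _read_tsv(text: str) -> list[dict[str, str]]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return list(reader)


@dataclass
class HaplogroupCall:
    """Result of classifying a variant list against the clade tree."""

    haplogroup: str
    basal: bool
    matched: dict[str, list[MtVariant]]  # per clade on the path: matched diagnostics
    missing: dict[str, list[MtVariant]]  # per clade on the path: absent diagnostics
    ambiguous: bool = False
    alternatives: tuple[str, ...] = ()

    @property
    def display_name(self) -> str:
        """Clade name with the basal star suffix (e.g. ``U6*``)."""
        return self.haplogroup + ("*" if self.basal else "")


def classify_haplogroup(
    variants: Sequence[MtVariant], tree: HaplogroupTree | None = None
) -> HaplogroupCall:
    """Deepest clade whose own diagnostic set is fully carried.

    Classification requires a full diagnostic match only at the assigned
    node; missing diagnostics on ancestral clades are reported, not fatal
    (back-mutations happen).  If two clades of equal depth match fully,
    the call is flagged ambiguous and the one with more matched diagnostics
    along its path (then lexicographic order) is reported.  The basal flag
    is set when no child clade of the call is fully matched.
    """
    tree = tree or load_haplogroup_tree()
    carried = {(v.position, v.alt) for v in variants}

    def own_match(name: str) -> tuple[list[MtVariant], list[MtVariant]]:
        hit, miss = [], []
        for d in tree.nodes[name].diagnostics:
            (hit if (d.position, d.alt) in carried else miss).append(d)
        return hit, miss

    full = [
        name
        for name in tree.nodes
        if name != ROOT_NAME and not own_match(name)[1]
    ]
    if not full:
        call_name = ROOT_NAME
    else:
        def path_score(name: str) -> int:
            return sum(len(own_match(n)[0]) for n in tree.path_to_root(name))

        max_depth = max(tree.depth(n) for n in full)
        deepest = sorted(
            (n for n in full if tree.depth(n) == max_depth),
            key=lambda n: (-path_score(n), n),
        )
        call_name = deepest[0]
    ambiguous = len(full) > 0 and len(
        [n for n in full if tree.depth(n) == tree.depth(call_name)]
    ) > 1

    matched, missing = {}, {}
    for name in tree.path_to_root(call_name):
        hit, miss = own_match(name)
        matched[name], missing[name] = hit, miss
    basal = not any(
        child in full for child in tree.children(call_name)
    ) and bool(tree.children(call_name))
    alternatives = tuple(
        n
        for n in full
        if n != call_name and tree.depth(n) == tree.depth(call_name)
    )
    return HaplogroupCall(
        haplogroup=call_name,
        basal=basal,
        matched=matched,
        missing=missing,
        ambiguous=ambiguous,
        alternatives=alternatives,
    )


# ---------------------------------------------------------------------------
# archaic diagnostic screening


@dataclass(frozen=True)
class ArchaicSite:
    position: int  # 1-based
    archaic_allele: str


@dataclass
class ArchaicScreenResult:
    n_sites: int
    n_matching: int
    matches: list[ArchaicSite]

    def __post_init__(self) -> None:
        if self.n_matching > self.n_sites:
            raise ValueError("matches cannot exceed screened sites")


def archaic_screen(
    variants: Sequence[MtVariant],
    sites: Sequence[ArchaicSite],
    reference: str | None = None,
) -> ArchaicScreenResult:
    """Count positions where the sample carries the archaic-specific allele.

    The sample allele at each screened position is the variant alt if the
    variant list covers the position, otherwise the reference base.
    """
    ref_seq = reference if reference is not None else load_reference()
    alt_at = {v.position: v.alt for v in variants}
    matches = [
        s
        for s in sites
        if alt_at.get(s.position, ref_seq[s.position - 1]) == s.archaic_allele
    ]
    return ArchaicScreenResult(
        n_sites=len(sites), n_matching=len(matches), matches=matches
    )


def derive_diagnostic_sites(
    archaic_genomes: Sequence[str], modern_panel: ReferencePanel
) -> list[ArchaicSite]:
    """Positions where all archaic genomes fix an allele absent in moderns.

    A site qualifies only if every archaic genome carries the same non-N
    allele and that allele has frequency exactly 0 in the modern panel.
    """
    if not archaic_genomes:
        raise ValueError("no archaic genomes supplied")
    from .reference import encode

    mats = np.vstack([encode(s) for s in archaic_genomes])
    L = mats.shape[1]
    if modern_panel.frequencies.shape[0] != L:
        raise ValueError("archaic/modern alignment length mismatch")
    fixed = (mats == mats[0:1, :]).all(axis=0) & (mats[0] < 4)
    covered = modern_panel.frequencies.sum(axis=1) > 0
    sites = []
    for i in np.nonzero(fixed & covered)[0]:
        allele = "ACGT"[mats[0, i]]
        if modern_panel.frequencies[i, mats[0, i]] == 0.0:
            sites.append(ArchaicSite(position=int(i) + 1, archaic_allele=allele))
    return sites


# ---------------------------------------------------------------------------
# private mutations


def private_mutations(
    variants: Sequence[MtVariant], panel: ReferencePanel
) -> list[MtVariant]:
    """Variants whose alt allele is absent (frequency 0) from the panel."""
    out = []
    for v in variants:
        if panel.frequencies[v.position - 1].sum() == 0:
            continue  # no panel data: cannot assert privacy
        if panel.allele_frequency(v.position, v.alt) == 0.0:
            out.append(v)
    return sorted(out)


# ---------------------------------------------------------------------------
# packaged PM1-style fixture


def load_pm1_variants(include_sources: bool = False):
    """The packaged 15-substitution basal-U6 haplotype fixture.

    Returns the variant list; with ``include_sources=True`` returns
    (variants, sources) where sources maps position -> 'stated'/'inferred'
    (only three of the fifteen substitutions of the real haplotype are
    public; the rest are synthetic placeholders, see the data file).
    """
    source = resources.files("mitopaleo.data").joinpath("pm1_variants.tsv")
    rows = _read_tsv(source.read_text())
    variants = []
    sources = {}
    for row in rows:
        v = MtVariant(position=int(row["position"]), ref=row["ref"], alt=row["alt"])
        variants.append(v)
        sources[v.position] = row["source"]
    validate_against_reference(variants)
    variants = sorted(variants)
    if include_sources:
        return variants, sources
    return variants
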
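"""Synthetic study objects: haplotypes, reference panels, archaic genomes.

Everything here is generated deterministically from the packaged synthetic
reference; nothing is downloaded.  These constructors define the study
conditions the package is exercised under: a 15-substitution basal-U6
sample haplotype, a 311-genome worldwide panel in which exactly two of the
sample's alleles are nearly private, a modern contaminant haplotype, and a
set of archaic genomes fixed for 63 derived alleles absent from moderns.
"""

from __future__ import annotations

import numpy as np

from .contamination import ReferencePanel
from .haplotyping import ArchaicSite, derive_diagnostic_sites, load_pm1_variants
from .reference import MT_LENGTH, TRANSITIONS, load_reference
from .simulate import SourceHaplotype
from .variants import MtVariant

#: panel size emulating a worldwide survey of mitogenomes
PANEL_SIZE = 311

#: number of archaic-diagnostic positions screened
N_ARCHAIC_SITES = 63

#: positions already used by packaged fixtures (kept clear of random draws)
_RESERVED = frozenset(
    [73, 150, 263, 437, 750, 793, 1438, 3197, 3348, 3688, 4965, 5081, 8701,
     9540, 10398, 10517, 11013, 11467, 12308, 12372, 12705, 13879, 15244,
     16169, 16172, 16189, 16219, 16223, 16270]
)


def pm1_haplotype() -> SourceHaplotype:
    """The packaged 15-substitution basal-U6 sample haplotype."""
    return SourceHaplotype.from_variants(load_pm1_variants(), label="PM1")


def random_haplotype(
    n_variants: int, seed: int, label: str, avoid: frozenset[int] = _RESERVED
) -> SourceHaplotype:
    """A haplotype with ``n_variants`` random transitions off the reference."""
    rng = np.random.default_rng(seed)
    ref = load_reference()
    positions: set[int] = set()
    while len(positions) < n_variants:
        p = int(rng.integers(1, MT_LENGTH + 1))
        if p not in avoid:
            positions.add(p)
    variants = [
        MtVariant(position=p, ref=ref[p - 1], alt=TRANSITIONS[ref[p - 1]])
        for p in sorted(positions)
    ]
    return SourceHaplotype.from_variants(variants, label=label)


def contaminant_haplotype(seed: int = 7, n_variants: int = 30) -> SourceHaplotype:
    """A modern-like contaminant differing from the reference at ~30 sites.

    None of its variant positions collide with the sample haplotype's, so it
    also differs from the sample at all of its own sites plus the sample's.
    """
    return random_haplotype(n_variants, seed=seed, label=f"contaminant{seed}")


def worldwide_panel(
    sample_variants: list[MtVariant] | None = None,
    n_genomes: int = PANEL_SIZE,
    n_background_sites: int = 60,
    rare_positions: tuple[int, ...] = (1438, 10517),
    common_frequency: float = 0.3,
    rare_frequency: float = 0.01,
    seed: int = 11,
) -> ReferencePanel:
    """A deterministic panel in which the sample has two nearly-private sites.

    Every sample variant allele segregates in the panel at
    ``common_frequency`` except at ``rare_positions``: the first rare
    position carries the sample allele at ``rare_frequency`` (< 5%) and any
    position listed but absent from the panel's carriers entirely (the
    private mutation, 10517 by default) at frequency 0.  Background
    diversity is added at ``n_background_sites`` further positions where
    the sample carries the reference allele.  Carrier sets are rotated
    across sites so panel genomes are not nested.
    """
    if sample_variants is None:
        sample_variants = load_pm1_variants()
    ref = load_reference()
    rng = np.random.default_rng(seed)

    # per-site derived allele and carrier count
    site_plan: list[tuple[int, str, int]] = []  # position, allele, n_carriers
    for v in sample_variants:
        if v.position == 10517:
            continue  # the private mutation: absent from the panel
        if v.position in rare_positions:
            count = max(int(round(rare_frequency * n_genomes)), 1)
        else:
            count = int(round(common_frequency * n_genomes))
        site_plan.append((v.position, v.alt, count))
    taken = {v.position for v in sample_variants}
    while len(site_plan) < len(sample_variants) - 1 + n_background_sites:
        p = int(rng.integers(1, MT_LENGTH + 1))
        if p in taken or p in _RESERVED:
            continue
        taken.add(p)
        base = ref[p - 1]
        freq = float(rng.uniform(0.05, 0.6))
        site_plan.append((p, TRANSITIONS[base], int(round(freq * n_genomes))))

    genomes = [list(ref) for _ in range(n_genomes)]
    for j, (pos, allele, count) in enumerate(site_plan):
        offset = (j * 37) % n_genomes  # rotate carriers to decorrelate sites
        for k in range(min(count, n_genomes)):
            genomes[(offset + k) % n_genomes][pos - 1] = allele
    return ReferencePanel.from_sequences(["".join(g) for g in genomes])


def mixture_panel(
    contaminant: SourceHaplotype | None = None,
    n_genomes: int = 8,
    n_variants: int = 25,
    seed: int = 23,
) -> ReferencePanel:
    """A small aligned panel for the mixture estimator, contaminant included.

    The panel stands in for the bank of worldwide mitogenomes reads are
    compared against; the true contaminant is its first sequence, so the
    mixture model's assumption (contaminant in the panel) holds in
    simulations.
    """
    contaminant = contaminant or contaminant_haplotype()
    seqs = [contaminant.sequence]
    for k in range(n_genomes - 1):
        seqs.append(
            random_haplotype(n_variants, seed=seed + k, label=f"panel{k}").sequence
        )
    return ReferencePanel.from_sequences(seqs)


def archaic_genomes(
    n_genomes: int = 10, n_sites: int = N_ARCHAIC_SITES, seed: int = 63
) -> list[str]:
    """Synthetic archaic mitogenomes fixed for derived alleles at ``n_sites``.

    All genomes share the same transversion at each chosen position
    (fixation, as required for a diagnostic site), at positions disjoint
    from the packaged haplotype fixtures.
    """
    rng = np.random.default_rng(seed)
    ref = load_reference()
    positions: set[int] = set()
    while len(positions) < n_sites:
        p = int(rng.integers(1, MT_LENGTH + 1))
        if p not in _RESERVED:
            positions.add(p)
    transversion = {"A": "C", "C": "A", "G": "T", "T": "G"}
    seq = list(ref)
    for p in positions:
        seq[p - 1] = transversion[ref[p - 1]]
    genome = "".join(seq)
    return [genome] * n_genomes


def packaged_archaic_sites() -> list[ArchaicSite]:
    """The packaged 63-position archaic diagnostic set.

    Derived, not hard-coded: :func:`derive_diagnostic_sites` is applied to
    the synthetic archaic genomes against a reference-only modern panel, so
    the set is exactly the positions where the archaics are fixed for an
    allele absent from moderns.
    """
    moderns = ReferencePanel.from_sequences([load_reference()] * 20)
    return derive_diagnostic_sites(archaic_genomes(), moderns)
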
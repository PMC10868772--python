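"""Reference taxonomy of the two study groups.

Grapevine (Vitaceae): the sampled non-hybrid taxa and named hybrids;
only the six most well-sampled species are highlighted separately in
figures, the rest grouped as "Other". Maracuya (Passifloraceae):
species clustered into morphology-based (not phylogenetic) morphotypes
A-G.
"""

from __future__ import annotations

__all__ = [
    "GRAPEVINE_TAXA",
    "GRAPEVINE_HYBRIDS",
    "GRAPEVINE_HIGHLIGHTED",
    "MORPHOTYPES",
    "morphotype_of",
]

#: Non-hybrid grapevine-dataset taxa (includes one non-Vitis vine relative).
GRAPEVINE_TAXA: tuple[str, ...] = (
    "Vitis riparia",
    "Vitis labrusca",
    "Vitis cinerea",
    "Vitis rupestris",
    "Vitis acerifolia",
    "Vitis amurensis",
    "Vitis vulpina",
    "Vitis aestivalis",
    "Vitis palmata",
    "Vitis coignetiae",
    "Ampelopsis glandulosa var. brevipedunculata",
)

GRAPEVINE_HYBRIDS: tuple[str, ...] = (
    "Vitis x andersonii",
    "Vitis x champinii",
    "Vitis x doaniana",
    "Vitis x novae-angliae",
)

#: The six most well-sampled species, shown individually in figures.
GRAPEVINE_HIGHLIGHTED: tuple[str, ...] = (
    "Vitis riparia",
    "Vitis acerifolia",
    "Vitis labrusca",
    "Vitis amurensis",
    "Vitis rupestris",
    "Vitis cinerea",
)

#: Morphology-based grouping of the maracuya species.
MORPHOTYPES: dict[str, tuple[str, ...]] = {
    "A": ("Passiflora coriacea", "Passiflora misera"),
    "B": (
        "Passiflora biflora",
        "Passiflora capsularis",
        "Passiflora micropetala",
        "Passiflora organensis",
        "Passiflora pohlii",
        "Passiflora rubra",
        "Passiflora tricuspis",
    ),
    "C": (
        "Passiflora caerulea",
        "Passiflora cincinnata",
        "Passiflora edmundoi",
        "Passiflora gibertii",
        "Passiflora hatschbachii",
        "Passiflora kermesina",
        "Passiflora mollissima",
        "Passiflora setacea",
        "Passiflora suberosa",
        "Passiflora tenuifila",
    ),
    "D": (
        "Passiflora amethystina",
        "Passiflora foetida",
        "Passiflora gracilis",
        "Passiflora morifolia",
    ),
    "E": (
        "Passiflora actinia",
        "Passiflora miersii",
        "Passiflora sidifolia",
        "Passiflora triloba",
    ),
    "F": (
        "Passiflora alata",
        "Passiflora edulis",
        "Passiflora ligularis",
        "Passiflora nitida",
        "Passiflora racemosa",
        "Passiflora villosa",
    ),
    "G": (
        "Passiflora coccinea",
        "Passiflora cristalina",
        "Passiflora galbana",
        "Passiflora malacophylla",
        "Passiflora maliformis",
        "Passiflora miniata",
        "Passiflora mucronata",
    ),
}


def morphotype_of(species: str) -> str:
    """Morphotype label (A-G) of a maracuya species."""
    for label, members in MORPHOTYPES.items():
        if species in members:
            return label
    raise KeyError(f"species {species!r} not in the morphotype table")
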
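"""Small packaged example dataset (synthetic, 6 plants x 20 fungi)."""

from __future__ import annotations

from importlib import resources

from .io import (
    CommunitySet,
    HostIncidence,
    PlantMetadata,
    read_communities,
    read_incidence,
    read_metadata,
    read_newick,
)
from .tree import PhyloTree

__all__ = ["load_small_fixture"]


def load_small_fixture() -> tuple[PhyloTree, HostIncidence, PlantMetadata, CommunitySet, PhyloTree]:
    """Load the shipped synthetic mini-dataset.

    Returns (fungal tree, incidence, metadata, communities, plant tree).
    The files were written by :func:`mycoverlap.simulate.write_fixture`
    from a fixed-seed :class:`~mycoverlap.simulate.SyntheticConfig`.
    """
    root = resources.files("mycoverlap").joinpath("data/fixture_small")
    with resources.as_file(root) as path:
        return (
            read_newick(path / "fungal_tree.nwk"),
            read_incidence(path / "incidence.tsv"),
            read_metadata(path / "metadata.tsv"),
            read_communities(path / "communities.tsv"),
            read_newick(path / "plant_tree.nwk"),
        )
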
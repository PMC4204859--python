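"""Site projection, clustering, labelling, near pairs and column profiles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronarch import fixtures as fx
from intronarch.gene_models import GeneModel, IntronSite, infer_intron_sites
from intronarch.projection import (
    AlignedSite,
    cds_to_residue,
    cluster_sites,
    column_profile,
    label_clusters,
    near_intron_pairs,
    presence_absence,
    project_site,
)


@pytest.mark.parametrize("offset,expected", [(0, (0, 0)), (152, (50, 2)), (174, (58, 0))])
def test_cds_to_residue(offset, expected):
    assert cds_to_residue(offset) == expected


class TestProjectSite:
    def test_gapless_identity(self):
        msa = {"sp": "A" * 100}
        site = IntronSite("sp", 152, 2, 500)
        assert project_site(site, msa).alignment_column == 50

    def test_gap_shifts_column(self):
        msa = {"sp": "M-AC"}
        site = IntronSite("sp", 3 * 1 + 1, 1, 50)  # residue 1
        assert project_site(site, msa).alignment_column == 2

    def test_offset_beyond_sequence(self):
        msa = {"sp": "MAC"}
        with pytest.raises(ValueError, match="sp"):
            project_site(IntronSite("sp", 30, 0, 50), msa)

    def test_unknown_species(self):
        with pytest.raises(KeyError):
            project_site(IntronSite("nope", 3, 0, 50), {"sp": "MAC"})

    @given(st.integers(1, 296), st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_gapless_roundtrip(self, offset, pad):
        """On gapless rows, column equals residue index for every offset."""
        msa = {"sp": "A" * (100 + pad)}
        aligned = project_site(IntronSite("sp", offset, offset % 3, 1), msa)
        assert aligned.alignment_column == aligned.residue_index == offset // 3


class TestClustering:
    def test_same_column_same_phase_merges(self):
        a = AlignedSite("s1", 5, 5, 0)
        b = AlignedSite("s2", 5, 5, 0)
        (cluster,) = cluster_sites([a, b])
        assert cluster.members == {"s1", "s2"}

    def test_phase_difference_separates(self):
        a = AlignedSite("s1", 5, 5, 0)
        b = AlignedSite("s2", 5, 5, 2)
        clusters = cluster_sites([a, b])
        assert len(clusters) == 2
        for c in clusters:
            assert len({s.phase for s in c.sites}) == 1

    def test_tolerance_chains_columns(self):
        sites = [AlignedSite(f"s{i}", c, c, 0) for i, c in enumerate([5, 6, 7, 30])]
        assert len(cluster_sites(sites, column_tolerance=0)) == 4
        assert len(cluster_sites(sites, column_tolerance=1)) == 2

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(0, 2)), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_cluster_count_monotone_in_tolerance(self, cols_phases):
        sites = [
            AlignedSite(f"s{i}", c, c, p) for i, (c, p) in enumerate(cols_phases)
        ]
        counts = [len(cluster_sites(sites, tol)) for tol in (0, 1, 2, 5)]
        assert counts == sorted(counts, reverse=True)
        # phase homogeneity is a hard invariant at any tolerance
        for tol in (0, 1, 2, 5):
            for c in cluster_sites(sites, tol):
                assert len({s.phase for s in c.sites}) == 1

    def test_projected_lepidoptera_sites_cocluster(self):
        """Identical gene structures on a conserved gapless alignment project
        to one cluster per junction across species."""
        species = ["S_frugiperda", "B_mori", "D_plexippus", "H_melpomene"]
        msa = {sp: "A" * 600 for sp in species}
        aligned = []
        for sp in species:
            model = GeneModel.from_exon_lengths(sp, [140, 160, 150, 152, 1084], [100] * 4)
            aligned += [project_site(s, msa) for s in infer_intron_sites(model)]
        clusters = cluster_sites(aligned)
        assert len(clusters) == 4
        assert all(c.members == set(species) for c in clusters)


class TestLabelling:
    def test_reference_numbering(self, table_clusters):
        labels = [c.label for c in table_clusters if c.label and c.label.endswith("l")]
        assert labels == [f"i{k}l" for k in range(1, 12)]

    def test_secondary_reference_contributes_missing_label(self, table_clusters):
        i3h = next(c for c in table_clusters if c.label == "i3h")
        assert i3h.members == {"A_cephalotes", "S_invicta", "C_floridanus", "H_saltator"}

    def test_chordate_numbering_counts_unshared_nterminal_sites(self, table_clusters):
        """Chordate-specific labels keep the full chordate gene numbering:
        the 4th and 7th human sites are i4c and i7c."""
        labels = {c.label for c in table_clusters}
        assert {"i4c", "i7c", "i1c", "i2c"} <= labels

    def test_unknown_reference_rejected(self, table_clusters):
        with pytest.raises(ValueError):
            label_clusters(table_clusters, "not_a_species", "z")

    def test_single_cluster_single_reference(self):
        clusters = cluster_sites([AlignedSite("sp", 3, 3, 1)])
        (labelled,) = label_clusters(clusters, "sp", "x")
        assert labelled.label == "i1x"


class TestNearPairs:
    def test_published_near_pair_distance(self, table_clusters):
        pairs = near_intron_pairs(table_clusters, max_nt_distance=32)
        assert ("i8l", "i7c", 24) in pairs

    def test_distant_sites_not_reported(self):
        clusters = cluster_sites(
            [AlignedSite("a", 10, 10, 0), AlignedSite("b", 50, 50, 0)]
        )
        assert near_intron_pairs(clusters, max_nt_distance=32) == []

    def test_same_site_not_a_pair(self):
        clusters = cluster_sites(
            [AlignedSite("a", 10, 10, 0), AlignedSite("b", 10, 10, 0)]
        )
        assert near_intron_pairs(clusters, max_nt_distance=32) == []

    def test_gap_aware_scaffold_distance(self):
        # scaffold has a gap between the two site columns: 2 residues apart
        # on the alignment but adjacent on the scaffold sequence
        msa = {"scaff": "AC-DE"}
        clusters = cluster_sites(
            [AlignedSite("x", 1, 1, 0), AlignedSite("y", 3, 3, 0)]
        )
        pairs = near_intron_pairs(clusters, 32, msa=msa, scaffold_species="scaff")
        assert pairs[0][2] == 3  # one scaffold residue apart
        pairs_nogap = near_intron_pairs(clusters, 32)
        assert pairs_nogap[0][2] == 6


class TestPresenceAbsence:
    def test_lepidoptera_cells(self, table_matrix):
        leps = ["S_frugiperda", "B_mori", "D_plexippus", "H_melpomene"]
        for sp in leps:
            for k in range(1, 12):
                expected = (
                    "absent" if (sp == "H_melpomene" and k == 9) else "present"
                )
                assert table_matrix.at[sp, f"i{k}l"] == expected

    def test_truncated_gene_unknown_upstream(self, table_matrix):
        assert table_matrix.at["L_longipalpis", "i3l"] == "unknown"
        assert table_matrix.at["L_longipalpis", "i7l"] == "present"
        assert table_matrix.at["L_longipalpis", "i9l"] == "absent"

    def test_empty_species_list(self, table_clusters):
        assert presence_absence(table_clusters, []).empty


class TestColumnProfile:
    def test_invariant_column(self):
        msa = {f"s{i}": "R" for i in range(5)}
        prof = column_profile(msa, [0])
        assert prof.at[0, "information_bits"] == pytest.approx(math.log2(20))

    def test_uniform_column_zero_bits(self):
        letters = "ACDEFGHIKLMNPQRSTVWY"
        msa = {f"s{i}": ch for i, ch in enumerate(letters)}
        prof = column_profile(msa, [0])
        assert prof.at[0, "information_bits"] == pytest.approx(0.0, abs=1e-12)

    def test_half_half_column(self):
        msa = {"a": "R", "b": "R", "c": "K", "d": "K"}
        prof = column_profile(msa, [0])
        assert prof.at[0, "information_bits"] == pytest.approx(math.log2(20) - 1)

    def test_all_gap_column_missing(self):
        msa = {"a": "-A", "b": "-C"}
        prof = column_profile(msa, [0, 1])
        assert math.isnan(prof.at[0, "information_bits"])
        assert prof.at[0, "gap_fraction"] == 1.0
        assert prof.at[1, "n_residues"] == 2
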
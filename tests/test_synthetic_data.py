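"""Synthetic-metagenome generator: determinism, planted truth, recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hadalmeta import traits
from hadalmeta._fasta import fasta_str
from hadalmeta.synthetic_data import (
    SyntheticConfig,
    TruthManifest,
    default_community,
    generate_annotation_tables,
    generate_bundle,
    generate_host_genomes,
    generate_read_assignments,
    plant_crispr_arrays,
    plant_prophages,
)
from tests._oracles import bf_hamming_scan, bf_kmer_freqs, bf_mae


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_hosts", -1),
            ("spacer_mismatch_rate", 1.5),
            ("unassigned_fraction", -0.1),
            ("abundance_concentration", 0.0),
            ("prophage_length_range", (100, 50)),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            SyntheticConfig(**{field: value})


class TestHostGenomes:
    def test_length_and_alphabet_contract(self, small_config):
        hosts, models = generate_host_genomes(small_config)
        assert len(hosts) == small_config.n_hosts
        for h in hosts:
            seq = h.concatenated()
            assert len(seq) == small_config.host_length
            assert set(seq) <= set("ACGT")
        assert set(models) == {h.genome_id for h in hosts}

    def test_same_seed_gives_identical_fasta_bytes(self, small_config):
        a, _ = generate_host_genomes(small_config)
        b, _ = generate_host_genomes(small_config)
        pairs = lambda hs: [(h.genome_id, h.concatenated()) for h in hs]
        assert fasta_str(pairs(a)) == fasta_str(pairs(b))

    def test_seeds_give_compositionally_distinct_hosts(self):
        """Tetranucleotide MAE across seeds exceeds the host-to-own-prophage
        distance, by brute-force 4-mer counting."""
        cfg1 = SyntheticConfig(seed=1, n_hosts=1, host_length=20_000,
                               prophage_length_range=(6_000, 8_000), n_decoys=0)
        cfg2 = dataclasses.replace(cfg1, seed=2)
        hosts1, _ = generate_host_genomes(cfg1)
        hosts2, _ = generate_host_genomes(cfg2)
        viruses, _ = plant_prophages(hosts1, cfg1)
        host1 = hosts1[0].concatenated()
        f_host1, _ = bf_kmer_freqs(host1)
        f_host2, _ = bf_kmer_freqs(hosts2[0].concatenated())
        cross_seed = bf_mae(f_host1, f_host2)
        for v in viruses:
            f_v, _ = bf_kmer_freqs(v.sequence)
            assert bf_mae(f_host1, f_v) < cross_seed


class TestProphages:
    def test_prophage_is_exact_host_substring(self, small_config):
        hosts, _ = generate_host_genomes(small_config)
        viruses, links = plant_prophages(hosts, small_config)
        by_id = {h.genome_id: h.concatenated() for h in hosts}
        planted = [v for v in viruses if not v.contig_id.startswith("decoy")]
        assert len(planted) == small_config.n_hosts * small_config.n_prophages_per_host
        for v in planted:
            (host_id,) = [h for vid, h in links if vid == v.contig_id]
            assert v.sequence in by_id[host_id]

    def test_zero_prophages_emits_only_decoys(self, small_config):
        cfg = dataclasses.replace(small_config, n_prophages_per_host=0)
        hosts, _ = generate_host_genomes(cfg)
        viruses, links = plant_prophages(hosts, cfg)
        assert links == set()
        assert all(v.contig_id.startswith("decoy") for v in viruses)

    def test_prophage_longer_than_host_rejected(self):
        cfg = SyntheticConfig(seed=1, n_hosts=1, host_length=1_000,
                              prophage_length_range=(2_000, 3_000))
        hosts, _ = generate_host_genomes(cfg)
        with pytest.raises(ValueError, match="shorter than"):
            plant_prophages(hosts, cfg)

    def test_prophage_closer_to_source_than_decoys(self, default_bundle):
        """Brute-force 4-mer MAE: planted virus vs source host is below its
        MAE to every other (decoy) host."""
        hosts = default_bundle.host_sequences()
        freqs = {hid: bf_kmer_freqs(seq)[0] for hid, seq in hosts.items()}
        for virus in default_bundle.viruses[:4]:  # a sample; full set is slow
            if virus.contig_id.startswith("decoy"):
                continue
            (src,) = [h for v, h in default_bundle.truth.prophage_links
                      if v == virus.contig_id]
            f_v, _ = bf_kmer_freqs(virus.sequence)
            d_src = bf_mae(f_v, freqs[src])
            for hid, f_h in freqs.items():
                if hid != src:
                    assert d_src < bf_mae(f_v, f_h)


class TestCrisprArrays:
    def test_exact_spacers_are_virus_substrings(self, small_config):
        hosts, _ = generate_host_genomes(small_config)
        viruses, _ = plant_prophages(hosts, small_config)
        modified, links = plant_crispr_arrays(hosts, viruses, small_config)
        assert links
        assert all(mm == 0 for _, _, mm in links)
        # at mismatch_rate 0 every planted spacer window exists verbatim:
        # the link's virus must contain a window matching inside the host
        vseqs = {v.contig_id: v.sequence for v in viruses}
        for vid, hid, _ in links:
            host_seq = next(h.concatenated() for h in modified if h.genome_id == hid)
            L = small_config.spacer_length
            found = any(
                vseqs[vid][i : i + L] in host_seq
                for i in range(len(vseqs[vid]) - L + 1)
            )
            assert found

    def test_zero_arrays_leaves_hosts_untouched(self, small_config):
        cfg = dataclasses.replace(small_config, n_spacer_arrays=0)
        hosts, _ = generate_host_genomes(cfg)
        viruses, _ = plant_prophages(hosts, cfg)
        modified, links = plant_crispr_arrays(hosts, viruses, cfg)
        assert links == set()
        assert [h.concatenated() for h in modified] == [h.concatenated() for h in hosts]

    def test_recorded_mismatch_counts_match_hamming_oracle(self):
        """With a nonzero mutation rate, each recorded mismatch count equals
        the true minimal Hamming distance of the planted spacer to its
        source virus (direct all-position comparison)."""
        cfg = SyntheticConfig(seed=3, n_hosts=2, host_length=8_000,
                              prophage_length_range=(2_000, 2_500),
                              n_spacer_arrays=3, spacer_mismatch_rate=0.05,
                              n_decoys=0)
        hosts, _ = generate_host_genomes(cfg)
        viruses, _ = plant_prophages(hosts, cfg)
        modified, links = plant_crispr_arrays(hosts, viruses, cfg)
        from hadalmeta.virus_host import detect_spacers

        spacers = detect_spacers({h.genome_id: h.concatenated() for h in modified})
        vseqs = {v.contig_id: v.sequence for v in viruses}
        # each truth (virus, host) pair must be explainable by a detected
        # spacer at exactly its best recorded Hamming distance
        for vid, hid in {(v, h) for v, h, _ in links}:
            expected = min(mm for v, h, mm in links if (v, h) == (vid, hid))
            candidates = [s for s in spacers if s.host_id == hid]
            assert candidates
            observed = min(bf_hamming_scan(s.sequence, vseqs[vid]) for s in candidates)
            assert observed == expected

    def test_no_viruses_is_an_error(self, small_config):
        hosts, _ = generate_host_genomes(small_config)
        with pytest.raises(ValueError, match="no viruses"):
            plant_crispr_arrays(hosts, [], small_config)


class TestAnnotations:
    def test_round_trip_recovers_planted_trait_labels(self, small_config):
        catalog = traits.default_catalog()
        table, labels = generate_annotation_tables(catalog, small_config)
        profiles = traits.classify_annotation_table(table, catalog)
        assert {p.genome_id for p in profiles} == set(labels)
        for p in profiles:
            assert p.flags() == labels[p.genome_id], p.genome_id

    def test_duplicate_pathway_names_rejected(self, small_config):
        catalog = traits.default_catalog()
        with pytest.raises(ValueError, match="duplicate"):
            generate_annotation_tables(catalog + [catalog[0]], small_config)


class TestReadAssignments:
    def test_single_taxon_no_unassigned(self):
        cfg = SyntheticConfig(seed=1, n_reads=50, unassigned_fraction=0.0)
        df = generate_read_assignments({"sk__Bacteria;p__OnlyOne": 1.0}, cfg)
        assert len(df) == 50
        assert (df["lineage"] == "sk__Bacteria;p__OnlyOne").all()

    def test_zero_reads_gives_empty_table(self):
        cfg = SyntheticConfig(seed=1, n_reads=0)
        assert generate_read_assignments({"sk__B;p__X": 1.0}, cfg).empty

    def test_negative_abundance_rejected(self):
        cfg = SyntheticConfig(seed=1)
        with pytest.raises(ValueError, match="negative"):
            generate_read_assignments({"a": -0.5, "b": 1.5}, cfg)

    def test_multinomial_recovery_within_one_percent(self):
        cfg = SyntheticConfig(seed=42, n_reads=100_000, unassigned_fraction=0.1)
        vec = default_community(cfg)
        df = generate_read_assignments(vec, cfg)
        assigned = df[df["lineage"] != "unclassified"]
        recovered = assigned["lineage"].value_counts(normalize=True)
        for taxon, p in vec.items():
            assert abs(recovered.get(taxon, 0.0) - p) < 0.01


class TestManifest:
    def test_truth_ids_resolve_and_vector_normalized(self, default_bundle):
        truth = default_bundle.truth
        host_ids = set(default_bundle.host_sequences())
        virus_ids = set(default_bundle.virus_sequences())
        for v, h in truth.prophage_links:
            assert v in virus_ids and h in host_ids
        for v, h, _ in truth.spacer_links:
            assert v in virus_ids and h in host_ids
        assert set(truth.trait_labels) == host_ids
        assert set(truth.composition_models) == host_ids
        assert abs(sum(truth.abundance_vector.values()) - 1.0) < 1e-9

    def test_manifest_json_round_trip(self, default_bundle):
        text = default_bundle.truth.to_json()
        back = TruthManifest.from_json(text)
        assert back.prophage_links == default_bundle.truth.prophage_links
        assert back.spacer_links == default_bundle.truth.spacer_links

    def test_bundle_is_reproducible(self, small_config):
        b1 = generate_bundle(small_config)
        b2 = generate_bundle(small_config)
        assert b1.host_sequences() == b2.host_sequences()
        assert b1.virus_sequences() == b2.virus_sequences()
        assert b1.truth.to_json() == b2.truth.to_json()
        pd.testing.assert_frame_equal(b1.reads, b2.reads)
        pd.testing.assert_frame_equal(b1.annotations, b2.annotations)


def test_joint_link_recovery_on_default_community(default_bundle):
    """Composition + similarity + CRISPR jointly recover >= 95 % of planted
    prophage links with no link to any unrelated host."""
    from hadalmeta import virus_host as vh

    hosts = default_bundle.host_sequences()
    viruses = default_bundle.virus_sequences()
    edges = []
    edges += vh.filter_similarity_links(vh.exact_substring_hits(viruses, hosts))
    edges += vh.match_spacers(vh.detect_spacers(hosts), viruses, max_mismatch=0)
    edges += vh.assign_by_composition(viruses, hosts)
    pairs = {e.pair for e in edges}
    truth_pairs = {(v, h) for v, h in default_bundle.truth.prophage_links} | {
        (v, h) for v, h, _ in default_bundle.truth.spacer_links
    }
    recovered = pairs & set(default_bundle.truth.prophage_links)
    assert len(recovered) / len(default_bundle.truth.prophage_links) >= 0.95
    assert pairs <= truth_pairs  # zero false links
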
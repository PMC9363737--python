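import numpy as np
import pandas as pd
import pytest

from gpbreed.genome_io import (
    GenotypeMatrix,
    LinkageMap,
    ParseError,
    code_and_impute,
    filter_markers_qc,
    read_genotypes,
    read_linkage_map,
    read_phenotypes,
    thin_markers,
)


class TestCodedCsv:
    def test_round_trip_identity(self, tmp_path):
        geno = GenotypeMatrix(["a", "b"], ["m1", "m2"], np.array([[1, -1], [0, 1]]))
        path = tmp_path / "g.csv"
        geno.to_csv(path)
        back = read_genotypes(path, dialect="coded-csv")
        assert back.accessions == geno.accessions
        assert back.markers == geno.markers
        np.testing.assert_array_equal(back.codes, geno.codes)

    def test_invalid_code_names_cell(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("accession,m1,m2\na,1,2\nb,0,1\n")
        with pytest.raises(ParseError, match="m2"):
            read_genotypes(path, dialect="coded-csv")

    def test_empty_entry_imputed_as_major_homozygote(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("accession,m1,m2\na,1,\nb,0,1\n")
        geno = read_genotypes(path, dialect="coded-csv")
        assert geno.codes[0, 1] == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_genotypes(tmp_path / "nope.csv")


class TestCodeAndImpute:
    def test_major_allele_coding_rule(self):
        # AA x7, AG x2, GG x1 -> A is major: AA->1, AG->0, GG->-1, missing->1
        calls = [["AA"] * 7 + ["AG"] * 2 + ["GG"], ["AA"] * 9 + [None]]
        raw = np.array(calls, dtype=object).T  # 10 accessions x 2 markers
        geno = code_and_impute(raw)
        expected_m1 = [1] * 7 + [0] * 2 + [-1]
        np.testing.assert_array_equal(geno.codes[:, 0], expected_m1)
        assert geno.codes[9, 1] == 1  # imputed missing

    def test_monomorphic_all_coded_one(self):
        raw = np.array([["AA"], ["AA"], ["AA"]], dtype=object)
        geno = code_and_impute(raw)
        assert (geno.codes == 1).all()

    def test_fifty_fifty_tie_prefers_lexicographic_allele(self):
        # 4 accessions: AA, AA, GG, GG -> tie; A < G so A is major
        raw = np.array([["AA"], ["AA"], ["GG"], ["GG"]], dtype=object)
        geno = code_and_impute(raw)
        np.testing.assert_array_equal(geno.codes[:, 0], [1, 1, -1, -1])

    def test_all_missing_marker_errors(self):
        raw = np.array([[None], [None]], dtype=object)
        with pytest.raises(ParseError, match="major allele undefined"):
            code_and_impute(raw)

    def test_codes_valid_and_imputation_bound(self, rng):
        alleles = np.array(["AA", "AG", "GG", None], dtype=object)
        raw = alleles[rng.integers(0, 4, size=(30, 20))]
        # ensure no all-missing column
        raw[0, :] = "AA"
        geno = code_and_impute(raw)
        assert np.isin(geno.codes, (-1, 0, 1)).all()
        n_missing = sum(1 for x in raw.ravel() if x is None)
        assert (geno.codes == 1).sum() >= n_missing


class TestVcf:
    VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\tsnp2\tC\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1
1\t300\tsnp3\tG\tGA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0
"""

    def test_het_call_becomes_code_zero(self, tmp_path):
        path = tmp_path / "x.vcf"
        path.write_text(self.VCF_TEXT)
        geno = read_genotypes(path, dialect="vcf")
        # indel record skipped
        assert geno.markers == ["snp1", "snp2"]
        assert geno.accessions == ["s1", "s2", "s3"]
        j = geno.markers.index("snp1")
        assert geno.codes[1, j] == 0  # s2 is 0/1
        # snp2: ALT T is the majority allele -> 1/1 codes as 1, het as 0
        k = geno.markers.index("snp2")
        np.testing.assert_array_equal(geno.codes[:, k], [1, 1, 0])


class TestLinkageMap:
    def test_out_of_order_input_is_sorted(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("marker,chrom,cM\nm3,1,5.0\nm1,1,1.0\nm2,1,3.0\n")
        lmap = read_linkage_map(path)
        assert lmap.markers == ["m1", "m2", "m3"]
        assert (lmap.frame["cM"].diff().dropna() >= 0).all()

    def test_duplicate_marker_errors(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("marker,chrom,cM\nm1,1,1.0\nm1,1,2.0\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_linkage_map(path)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("marker,chrom,cM\n")
        with pytest.raises(ParseError, match="empty"):
            read_linkage_map(path)

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("marker,position\nm1,1.0\n")
        with pytest.raises(ParseError, match="columns"):
            read_linkage_map(path)

    def test_round_trip(self, tmp_path, small_dataset):
        lmap = small_dataset["lmap"]
        path = tmp_path / "map.csv"
        lmap.to_csv(path)
        back = read_linkage_map(path)
        assert back.markers == lmap.markers
        np.testing.assert_allclose(back.frame["cM"], lmap.frame["cM"])


class TestPhenotypes:
    def test_row_with_missing_trait_dropped(self, tmp_path, caplog):
        path = tmp_path / "ph.csv"
        path.write_text("accession,yld,ph\na,5.0,1.0\nb,,2.0\nc,6.0,3.0\n")
        import logging

        with caplog.at_level(logging.INFO, logger="gpbreed.genome_io"):
            table = read_phenotypes(path)
        assert table.accessions == ["a", "c"]
        assert any("dropped 1" in rec.message for rec in caplog.records)

    def test_unknown_trait_errors(self, tmp_path):
        path = tmp_path / "ph.csv"
        path.write_text("accession,yld\na,5.0\n")
        with pytest.raises(ParseError, match="unknown trait"):
            read_phenotypes(path, traits=["yld", "ft"])

    def test_duplicate_accession_errors(self, tmp_path):
        path = tmp_path / "ph.csv"
        path.write_text("accession,yld\na,5.0\na,6.0\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_phenotypes(path)


class TestThinMarkers:
    def _map(self, positions, chrom="1"):
        frame = pd.DataFrame(
            {"marker": [f"m{i}" for i in range(len(positions))], "chrom": chrom, "cM": positions}
        ).set_index("marker")
        return LinkageMap(frame)

    def test_one_marker_per_occupied_interval(self, rng):
        lmap = self._map([0.00, 0.05, 0.12, 0.19, 0.31])
        chosen = thin_markers(lmap, 0.1, rng)
        assert len(chosen) == 3
        assert chosen[0] in {"m0", "m1"}
        assert chosen[1] in {"m2", "m3"}
        assert chosen[2] == "m4"
        # output preserves map order
        order = {m: i for i, m in enumerate(lmap.markers)}
        assert chosen == sorted(chosen, key=order.__getitem__)

    def test_interval_larger_than_span_keeps_one_per_chromosome(self, rng):
        frame = pd.DataFrame(
            {
                "marker": ["a1", "a2", "b1", "b2"],
                "chrom": ["1", "1", "2", "2"],
                "cM": [0.0, 50.0, 10.0, 20.0],
            }
        ).set_index("marker")
        chosen = thin_markers(LinkageMap(frame), 1000.0, rng)
        assert len(chosen) == 2

    def test_fixed_seed_is_deterministic(self, small_dataset):
        lmap = small_dataset["lmap"]
        a = thin_markers(lmap, 5.0, np.random.default_rng(7))
        b = thin_markers(lmap, 5.0, np.random.default_rng(7))
        assert a == b

    def test_size_equals_occupied_intervals(self, small_dataset, rng):
        lmap = small_dataset["lmap"]
        interval = 7.5
        expected = 0
        for chrom in lmap.chromosomes():
            pos = lmap.frame.loc[lmap.frame["chrom"] == chrom, "cM"].to_numpy()
            expected += len(set(np.floor(pos / interval).astype(int)))
        assert len(thin_markers(lmap, interval, rng)) == expected

    def test_invalid_interval(self, small_dataset, rng):
        with pytest.raises(ValueError):
            thin_markers(small_dataset["lmap"], 0.0, rng)


def test_filter_markers_qc_drops_rare_and_gappy_markers():
    frame = pd.DataFrame(
        {
            "common": ["AA", "AG", "GG", "AG", "AA", "GG", "AA", "AG", "AA", "GG"],
            "rare": ["AA"] * 9 + ["AG"],  # MAF 0.05 < threshold boundary is kept; use stricter
            "gappy": [None, None, "AA", "AA", "AA", "AA", "AA", "AA", "AA", "AA"],
        }
    )
    kept = filter_markers_qc(frame, max_missing_rate=0.05, min_maf=0.10)
    assert list(kept.columns) == ["common"]
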
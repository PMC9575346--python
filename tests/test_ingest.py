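import numpy as np
import pandas as pd
import pytest

from snpdiffnet import (
    GenotypeMatrix,
    SnpGeneMap,
    compute_gene_scores,
    read_genotypes,
    read_snp_gene_map,
)
from snpdiffnet.ingest import GenotypeParseError


def write(path, text):
    path.write_text(text)
    return path


class TestDelimited:
    def test_roundtrip_small_table_with_missing(self, tmp_path):
        p = write(
            tmp_path / "g.csv",
            "sample_id,label,rs1,rs2\ns1,0,0,1\ns2,1,2,0\ns3,1,1,\n",
        )
        g = read_genotypes(p)
        assert (g.n_samples, g.n_snps) == (3, 2)
        assert g.snp_ids == ["rs1", "rs2"]
        assert np.isnan(g.values[2, 1])
        assert np.nansum(np.isnan(g.values)) == 1
        assert list(g.y) == [0, 1, 1]

    def test_tab_dialect_and_covariates(self, tmp_path):
        p = write(
            tmp_path / "g.tsv",
            "sample_id\tlabel\tbmi\trs1\ns1\t0\t22.5\t0\ns2\t1\t30.1\t2\n",
        )
        g = read_genotypes(p, covariates=["bmi"])
        assert list(g.covariates.columns) == ["bmi"]
        assert g.snp_ids == ["rs1"]

    def test_duplicate_snp_header_names_the_id(self, tmp_path):
        p = write(tmp_path / "g.csv", "sample_id,label,rs1,rs1\ns1,0,0,1\n")
        with pytest.raises(GenotypeParseError, match="rs1"):
            read_genotypes(p)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = write(tmp_path / "g.csv", "sample_id,label,rs1\ns1,0,0\ns1,1,1\n")
        with pytest.raises(GenotypeParseError, match="s1"):
            read_genotypes(p)

    def test_out_of_range_value_located(self, tmp_path):
        p = write(tmp_path / "g.csv", "sample_id,label,rs1\ns1,0,0\ns2,1,3\n")
        with pytest.raises(GenotypeParseError, match="rs1"):
            read_genotypes(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_genotypes(tmp_path / "absent.csv")


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t./.
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0\t./1\t1|1
"""


class TestVcf:
    def test_gt_coding_and_missing(self, tmp_path):
        vcf = write(tmp_path / "g.vcf", VCF_TEXT)
        st = write(
            tmp_path / "samples.csv",
            "sample_id,label,bmi\ns1,0,21\ns2,1,25\ns3,1,28\n",
        )
        g = read_genotypes(vcf, dialect="vcf", sample_table=st)
        # 0/1 -> 1, 1/1 -> 2, ./. -> missing, half-call ./1 -> missing, 1|1 -> 2
        assert g.values[0, 0] == 1 and g.values[1, 0] == 2 and np.isnan(g.values[2, 0])
        assert g.values[0, 1] == 0 and np.isnan(g.values[1, 1]) and g.values[2, 1] == 2
        assert list(g.y) == [0, 1, 1]
        assert list(g.covariates.columns) == ["bmi"]

    def test_vcf_requires_sample_table(self, tmp_path):
        vcf = write(tmp_path / "g.vcf", VCF_TEXT)
        with pytest.raises(GenotypeParseError, match="sample table"):
            read_genotypes(vcf, dialect="vcf")


class TestSnpGeneMap:
    def test_snp_in_two_genes_rejected(self):
        with pytest.raises(ValueError, match="rs1"):
            SnpGeneMap.from_pairs([("rs1", "LEP"), ("rs1", "LEPR")])

    def test_read_write_roundtrip(self, tmp_path):
        m = SnpGeneMap.from_pairs([("rs1", "LEP"), ("rs2", "LEP"), ("rs3", "LEPR")])
        m.write(tmp_path / "map.tsv")
        m2 = read_snp_gene_map(tmp_path / "map.tsv")
        assert m2.snp_to_gene == m.snp_to_gene
        assert m2.genes == ["LEP", "LEPR"]
        assert m2.snps_for("LEP") == ["rs1", "rs2"]


def make_gm(values, n_cov=0, y=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if y is None:
        y = [i % 2 for i in range(n)]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"rs{j}" for j in range(values.shape[1])],
        values=values,
        y=y,
        covariates=pd.DataFrame(),
    )


class TestGeneScores:
    def test_single_snp_gene_is_identity(self):
        g = make_gm([[0], [1], [2], [1]])
        s = compute_gene_scores(g, {"rs0": "LEP"})
        assert np.allclose(s.column("LEP"), [0, 1, 2, 1])

    def test_mean_of_codes(self):
        g = make_gm([[0, 1, 2], [2, 2, 2]])
        s = compute_gene_scores(g, {f"rs{j}": "LEP" for j in range(3)})
        assert np.allclose(s.column("LEP"), [1.0, 2.0])

    def test_missing_policies_match_hand_and_bruteforce(self):
        # 2 samples x 2 SNPs of one gene, cell (1, rs1) missing
        vals = np.array([[0.0, 2.0], [1.0, np.nan]])
        g = make_gm(vals)
        m = {"rs0": "G", "rs1": "G"}
        drop = compute_gene_scores(g, m, "drop_from_mean")
        imp = compute_gene_scores(g, m, "per_snp_mean_impute")
        # hand-evaluated: drop -> mean of non-missing; impute -> rs1 column mean = 2
        assert np.allclose(drop.column("G"), [1.0, 1.0])
        assert np.allclose(imp.column("G"), [1.0, 1.5])

        # independent brute force over the four cells
        def brute(policy):
            out = []
            col_mean = {j: np.nanmean(vals[:, j]) for j in range(2)}
            for i in range(2):
                row = []
                for j in range(2):
                    v = vals[i, j]
                    if np.isnan(v) and policy == "impute":
                        v = col_mean[j]
                    row.append(v)
                row = [v for v in row if not np.isnan(v)]
                out.append(sum(row) / len(row))
            return out

        assert np.allclose(drop.column("G"), brute("drop"))
        assert np.allclose(imp.column("G"), brute("impute"))

    def test_policies_coincide_without_missing(self, rng):
        vals = rng.integers(0, 3, size=(20, 6)).astype(float)
        g = make_gm(vals)
        m = {f"rs{j}": ("A" if j < 3 else "B") for j in range(6)}
        a = compute_gene_scores(g, m, "drop_from_mean")
        b = compute_gene_scores(g, m, "per_snp_mean_impute")
        assert np.array_equal(a.scores, b.scores)

    def test_sample_permutation_equivariance_and_snp_order_invariance(self, rng):
        vals = rng.integers(0, 3, size=(15, 4)).astype(float)
        g = make_gm(vals)
        m = {f"rs{j}": "G" for j in range(4)}
        base = compute_gene_scores(g, m)
        perm = rng.permutation(15)
        g2 = GenotypeMatrix(
            sample_ids=[g.sample_ids[i] for i in perm],
            snp_ids=g.snp_ids,
            values=vals[perm],
            y=g.y[perm],
        )
        assert np.allclose(compute_gene_scores(g2, m).scores, base.scores[perm])
        # SNP column order within the gene does not matter
        order = [2, 0, 3, 1]
        g3 = make_gm(vals[:, order])
        m3 = {f"rs{j}": "G" for j in range(4)}
        assert np.allclose(compute_gene_scores(g3, m3).scores, base.scores)

    def test_scores_bounded_and_zero_cohort(self):
        g = make_gm(np.zeros((6, 4)))
        s = compute_gene_scores(g, {f"rs{j}": "G" for j in range(4)})
        assert np.all(s.scores == 0)

    def test_gene_with_no_snp_present_errors(self):
        g = make_gm([[0], [1]])
        with pytest.raises(ValueError, match="LEPR"):
            compute_gene_scores(g, {"rs0": "LEP", "rsX": "LEPR"})

    def test_all_missing_sample_warns_and_is_nan(self):
        g = make_gm([[np.nan], [1.0]])
        with pytest.warns(UserWarning, match="no usable"):
            s = compute_gene_scores(g, {"rs0": "G"}, "drop_from_mean")
        assert np.isnan(s.column("G")[0])
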
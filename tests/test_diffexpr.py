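import numpy as np
import pytest

from stagenet.core import ExpressionMatrix, StagenetError, StageLabels
from stagenet.diffexpr import (
    bh_adjust,
    differential_expression,
    multi_group_contrasts,
    progressive_genes,
    rank_correlation,
)


def two_group(values_a, values_b, genes=None):
    """Build a matrix + labels with 'control' (a) and 'tumor' (b) groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    vals = np.hstack([a, b])
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    samples = [f"c{j}" for j in range(a.shape[1])] + [f"t{j}" for j in range(b.shape[1])]
    mapping = {s: ("control" if s.startswith("c") else "tumor") for s in samples}
    return (
        ExpressionMatrix(vals, genes, samples),
        StageLabels(mapping, control="control"),
    )


def brute_force_bh(p):
    """Independent closed form: adjusted_i = min_{j >= i} (m * p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBenjaminiHochberg:
    def test_textbook_vector_all_collapse(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_short_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 11))
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestDifferentialExpression:
    def test_exact_fourfold_gives_lfc_two(self):
        # log2 values differing by exactly 2 with zero within-group variance
        m, labels = two_group(np.full((1, 3), 3.0), np.full((1, 3), 5.0))
        de = differential_expression(m, labels, "tumor")
        assert de.lfc[0] == pytest.approx(2.0)

    def test_identical_groups_all_ns(self):
        m, labels = two_group(np.full((4, 3), 2.0), np.full((4, 3), 2.0))
        de = differential_expression(m, labels, "tumor")
        assert np.allclose(de.lfc, 0.0)
        assert (de.status == "ns").all()

    def test_status_requires_both_lfc_and_fdr(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5, 0.1, (30, 10))
        b = rng.normal(5, 0.1, (30, 10))
        b[0] += 3.0   # big shift -> over
        b[1] += 0.5   # significant but below |LFC| threshold -> ns
        m, labels = two_group(a, b)
        de = differential_expression(m, labels, "tumor", lfc_threshold=2.0)
        assert de.status[0] == "over"
        assert de.status[1] == "ns"
        under = b.copy()
        m2, labels2 = two_group(b, a)  # reversed: gene 0 drops by 3
        de2 = differential_expression(m2, labels2, "tumor")
        assert de2.status[0] == "under"

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(1)
        m, labels = two_group(rng.normal(5, 1, (20, 6)), rng.normal(6, 1, (20, 6)))
        fwd = differential_expression(m, labels, "tumor")
        rev = differential_expression(
            m, labels, "control", baseline_phenotype="tumor"
        )
        np.testing.assert_allclose(fwd.lfc, -rev.lfc)

    def test_absent_phenotype_rejected(self):
        m, labels = two_group(np.ones((2, 3)), np.ones((2, 3)))
        with pytest.raises(StagenetError, match="absent"):
            differential_expression(m, labels, "stage_ix")


class TestMultiGroup:
    def test_pair_count_is_n_choose_2(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(5, 1, (10, 15))
        samples = [f"s{j}" for j in range(15)]
        mapping = {s: f"ph{j // 3}" for j, s in enumerate(samples)}
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(10)], samples)
        labels = StageLabels(mapping, control="ph0")
        out = multi_group_contrasts(m, labels)
        assert len(out) == 10  # C(5,2)
        assert all(de.lfc_threshold == 0.5 for de in out.values())

    def test_two_phenotypes_single_contrast(self):
        m, labels = two_group(np.ones((3, 3)), np.ones((3, 3)))
        assert len(multi_group_contrasts(m, labels)) == 1


class TestRankCorrelation:
    def _de(self, lfcs):
        m, labels = two_group(
            np.zeros((len(lfcs), 2)), np.array(lfcs, dtype=float)[:, None] * [1, 1]
        )
        return differential_expression(m, labels, "tumor")

    def test_self_correlation_is_one(self):
        de = self._de([1.0, 2.0, 3.0])
        assert rank_correlation(de, de) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        assert rank_correlation(self._de([1, 2, 3]), self._de([3, 2, 1])) == pytest.approx(-1.0)

    def test_one_swap_gives_point_eight(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/60
        assert rank_correlation(
            self._de([1, 2, 3, 4]), self._de([1, 3, 2, 4])
        ) == pytest.approx(0.8, abs=1e-10)

    def test_too_few_shared_genes_rejected(self):
        with pytest.raises(StagenetError, match=">= 3"):
            rank_correlation(self._de([1, 2]), self._de([2, 1]))


def test_tumor_signatures_correlate_above_permuted_label_null():
    """Stages sharing planted modules have concordant DE signatures;
    destroying the stage structure by permuting labels removes it."""
    from stagenet.preprocess import normalize
    from stagenet.simulate import generate_cohort, make_study_config

    cfg = make_study_config(3, samples_per_phenotype=40)
    matrix, _, labels, _ = generate_cohort(cfg)
    norm = normalize(matrix).normalized
    de_i = differential_expression(norm, labels, "stage_i")
    de_iv = differential_expression(norm, labels, "stage_iv")
    rho = rank_correlation(de_i, de_iv)

    rng = np.random.default_rng(0)
    samples = list(labels.mapping)
    shuffled = rng.permutation([labels.mapping[s] for s in samples])
    null_labels = StageLabels(dict(zip(samples, shuffled)), control="control")
    de_i_null = differential_expression(norm, null_labels, "stage_i")
    rho_null = rank_correlation(de_i_null, de_iv)
    assert rho > 0
    assert rho > rho_null


class TestProgressiveGenes:
    def _ordered(self, gene_rows, n=12, n_ph=4):
        """gene_rows: per-gene per-phenotype mean levels; Gaussian jitter."""
        rng = np.random.default_rng(0)
        blocks, samples, mapping = [], [], {}
        phenos = [f"p{t}" for t in range(n_ph)]
        for t, ph in enumerate(phenos):
            level = np.array([row[t] for row in gene_rows], dtype=float)
            blocks.append(level[:, None] + rng.normal(0, 0.05, (len(gene_rows), n)))
            ids = [f"{ph}_s{j}" for j in range(n)]
            samples += ids
            mapping.update({s: ph for s in ids})
        m = ExpressionMatrix(
            np.hstack(blocks), [f"g{i}" for i in range(len(gene_rows))], samples
        )
        return m, StageLabels(mapping, control=phenos[0]), phenos

    def test_monotone_and_significant_detected_with_direction(self):
        m, labels, phenos = self._ordered(
            [[0, 1, 2, 3], [3, 2, 1, 0], [1, 1, 1, 1]]
        )
        out = progressive_genes(m, labels, phenos)
        found = {p.gene: p.direction for p in out}
        assert found == {"g0": "up", "g1": "down"}

    def test_constant_gene_never_reported(self):
        m, labels, phenos = self._ordered([[2, 2, 2, 2]])
        m.values[0] = 2.0  # exactly constant
        assert progressive_genes(m, labels, phenos) == []

    def test_monotone_but_one_flat_step_not_reported(self):
        # g0 monotone in means but p2->p3 difference is negligible vs
        # jitter: its consecutive test is non-significant.
        m, labels, phenos = self._ordered([[0, 1, 2, 2.001]])
        assert progressive_genes(m, labels, phenos) == []

    def test_requires_three_phenotypes_and_two_samples(self):
        m, labels, phenos = self._ordered([[0, 1, 2, 3]])
        with pytest.raises(StagenetError):
            progressive_genes(m, labels, phenos[:2])
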
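"""Filtering, Dirichlet-multinomial tests and stage-wise adjustment."""

import numpy as np
import pandas as pd
import pytest

from drnakit.datatypes import AbundanceMatrix
from drnakit.dtu import (
    _fit_dm,
    dm_gene_test,
    dm_transcript_tests,
    dtu_test_all,
    filter_counts,
    stagewise_adjust,
)
from drnakit.datatypes import FormatError

COND = np.array(["bacterial"] * 6 + ["viral"] * 6)
SAMPLES = [f"B{i}" for i in range(1, 7)] + [f"V{i}" for i in range(1, 7)]


def tx_matrix(values, tx_ids):
    return AbundanceMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=tx_ids,
                     columns=SAMPLES),
        unit="counts", level="transcript",
    )


def brute_filter(values, tx_ids, tx2gene, msg, msf, mg, mf):
    """Literal re-implementation of the filter rules."""
    df = pd.DataFrame(values, index=tx_ids, columns=SAMPLES)
    keep = []
    for tid in tx_ids:
        gene = tx2gene[tid]
        gene_rows = [t for t in tx_ids if tx2gene[t] == gene]
        gene_total = df.loc[gene_rows].sum(axis=0)
        gene_ok = (gene_total >= mg).sum() >= msg
        tx_ok = (df.loc[tid] >= mf).sum() >= msf
        keep.append(gene_ok and tx_ok)
    kept = [t for t, k in zip(tx_ids, keep) if k]
    per_gene = pd.Series([tx2gene[t] for t in kept]).value_counts()
    return [t for t in kept if per_gene[tx2gene[t]] >= 2]


class TestFilterCounts:
    def test_constructed_survivor_set(self):
        """Gene A passes every rule, gene B fails the gene-total rule."""
        values = np.vstack([
            np.full(12, 20.0),   # A.t1
            np.full(12, 15.0),   # A.t2
            np.full(12, 2.0),    # B.t1 (gene total 4 < 10)
            np.full(12, 2.0),    # B.t2
        ])
        matrix = tx_matrix(values, ["A.t1", "A.t2", "B.t1", "B.t2"])
        tx2gene = {"A.t1": "A", "A.t2": "A", "B.t1": "B", "B.t2": "B"}
        out = filter_counts(matrix, tx2gene)
        assert list(out.feature_ids) == ["A.t1", "A.t2"]

    def test_all_zero_matrix_is_emptied(self):
        matrix = tx_matrix(np.zeros((2, 12)), ["A.t1", "A.t2"])
        out = filter_counts(matrix, {"A.t1": "A", "A.t2": "A"})
        assert len(out.data) == 0

    def test_zero_thresholds_drop_only_single_transcript_genes(self):
        values = np.ones((3, 12))
        matrix = tx_matrix(values, ["A.t1", "A.t2", "B.t1"])
        tx2gene = {"A.t1": "A", "A.t2": "A", "B.t1": "B"}
        out = filter_counts(matrix, tx2gene, 0, 0, 0, 0)
        assert set(out.feature_ids) == {"A.t1", "A.t2"}

    def test_unmapped_transcript_rejected(self):
        matrix = tx_matrix(np.ones((1, 12)), ["X.t1"])
        with pytest.raises(FormatError, match="without gene mapping"):
            filter_counts(matrix, {})

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n_genes = int(rng.integers(2, 8))
            tx_ids, tx2gene = [], {}
            for g in range(n_genes):
                for t in range(int(rng.integers(1, 5))):
                    tid = f"G{g}.t{t}"
                    tx_ids.append(tid)
                    tx2gene[tid] = f"G{g}"
            values = rng.poisson(8, size=(len(tx_ids), 12)).astype(float)
            msg = int(rng.integers(0, 13))
            msf = int(rng.integers(0, 13))
            mg = float(rng.integers(0, 30))
            mf = float(rng.integers(0, 15))
            out = filter_counts(tx_matrix(values, tx_ids), tx2gene,
                                msg, msf, mg, mf)
            assert list(out.feature_ids) == brute_filter(
                values, tx_ids, tx2gene, msg, msf, mg, mf
            )


class TestDmGeneTest:
    def test_identical_condition_columns_give_null_result(self):
        block = np.array([[10, 20, 30, 10, 20, 30],
                          [5, 5, 5, 5, 5, 5]])
        counts = np.hstack([block, block])
        lr, df, p = dm_gene_test(counts, COND)
        assert lr == pytest.approx(0.0, abs=1e-6)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_infinite_precision_limit_equals_multinomial_lrt(self):
        """At fixed precision 1e6 the DM LRT converges to the multinomial
        likelihood-ratio statistic (relative difference < 1%)."""
        rng = np.random.default_rng(3)
        counts = rng.multinomial(400, [0.5, 0.3, 0.2], size=12).T.astype(float)
        lr, _, _ = dm_gene_test(counts, COND, precision=1e6)
        pooled = counts.sum(axis=1) / counts.sum()
        g = 0.0
        for label in ("bacterial", "viral"):
            sub = counts[:, COND == label]
            obs = sub.sum(axis=1)
            phat = obs / obs.sum()
            mask = obs > 0
            g += 2.0 * (obs[mask] * np.log(phat[mask] / pooled[mask])).sum()
        assert lr == pytest.approx(g, rel=0.01)

    def test_alternative_likelihood_dominates_null(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(20, size=(3, 12)).astype(float) + 1
        per = counts.T
        ll0, p0 = _fit_dm([per])
        s0 = float(np.exp(p0[0]))
        groups = [per[COND == lab] for lab in np.unique(COND)]
        init1 = np.concatenate([[p0[0]], np.tile(p0[1:3], 2)])
        ll1, _ = _fit_dm(groups, fixed_precision=s0, init=init1)
        ll0f, _ = _fit_dm([per], fixed_precision=s0, init=p0)
        assert ll1 >= ll0f - 1e-8

    def test_single_transcript_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            dm_gene_test(np.ones((1, 12)), COND)

    def test_proportion_swap_is_detected(self):
        rng = np.random.default_rng(5)
        bac = rng.multinomial(300, [0.8, 0.1, 0.1], size=6).T
        vir = rng.multinomial(300, [0.1, 0.8, 0.1], size=6).T
        lr, df, p = dm_gene_test(np.hstack([bac, vir]).astype(float), COND)
        assert df == 2
        assert p < 1e-3


class TestTranscriptTests:
    def test_two_transcript_collapse_is_idempotent(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(30, size=(2, 12)).astype(float) + 1
        p_tx = dm_transcript_tests(counts, COND)
        _, _, p_gene = dm_gene_test(counts, COND)
        np.testing.assert_allclose(p_tx, p_gene, rtol=1e-4)

    def test_permuting_transcripts_permutes_outputs(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(25, size=(3, 12)).astype(float) + 1
        p = dm_transcript_tests(counts, COND)
        p_perm = dm_transcript_tests(counts[[2, 0, 1]], COND)
        # softmax reference-category numerics leave ~1e-4 relative wiggle
        np.testing.assert_allclose(p_perm, p[[2, 0, 1]], rtol=1e-3)


class TestStagewise:
    def test_hand_worked_single_gene_example(self):
        gene_p = pd.DataFrame({"gene_id": ["g"], "p_gene": [0.01]})
        tx_p = pd.DataFrame({
            "gene_id": ["g", "g"], "transcript_id": ["t1", "t2"],
            "p_tx": [0.01, 0.5],
        })
        out = stagewise_adjust(gene_p, tx_p).set_index("transcript_id")
        # m = R = 1 and Shaffer at K=2 leaves both p unscaled
        assert out.loc["t1", "stagewise_adj_p"] == pytest.approx(0.01)
        assert out.loc["t2", "stagewise_adj_p"] == pytest.approx(0.5)

    def test_no_screened_genes_confirms_nothing(self):
        gene_p = pd.DataFrame({"gene_id": ["g1", "g2"],
                               "p_gene": [0.4, 0.9]})
        tx_p = pd.DataFrame({
            "gene_id": ["g1", "g1", "g2", "g2"],
            "transcript_id": ["a", "b", "c", "d"],
            "p_tx": [0.001, 0.2, 0.3, 0.4],
        })
        out = stagewise_adjust(gene_p, tx_p)
        assert out["stagewise_adj_p"].isna().all()
        assert not out["screened"].any()

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(20)]
        gene_p = pd.DataFrame({"gene_id": genes,
                               "p_gene": rng.random(20) * 0.2})
        tx_rows = []
        for g in genes:
            for t in range(int(rng.integers(2, 5))):
                tx_rows.append({"gene_id": g, "transcript_id": f"{g}.t{t}",
                                "p_tx": rng.random()})
        out = stagewise_adjust(gene_p, pd.DataFrame(tx_rows))
        confirmed = out.dropna(subset=["stagewise_adj_p"])
        assert (confirmed["stagewise_adj_p"] >= confirmed["p_tx"] - 1e-12).all()

    def test_transcripts_of_unknown_gene_rejected(self):
        gene_p = pd.DataFrame({"gene_id": ["g1"], "p_gene": [0.01]})
        tx_p = pd.DataFrame({"gene_id": ["zz"], "transcript_id": ["t"],
                             "p_tx": [0.1]})
        with pytest.raises(ValueError, match="outside the screen"):
            stagewise_adjust(gene_p, tx_p)


class TestEndToEnd:
    def test_injected_dtu_gene_screened_and_confirmed(self):
        from drnakit.simulate import SimConfig, simulate_isoform_counts

        cfg = SimConfig(
            n_genes=10, n_mito_genes=0, isoform_total_mean=1000.0,
            dm_precision=100.0,
            dtu_genes={
                "G00005": ((0.8, 0.15, 0.05), (0.05, 0.15, 0.8)),
                "G00006": ((0.9, 0.05, 0.05), (0.05, 0.05, 0.9)),
            },
            seed=9,
        )
        matrix, truth = simulate_isoform_counts(cfg)
        tx2gene = truth.transcripts.set_index("transcript_id")[
            "gene_id"
        ].to_dict()
        meta = cfg.metadata()
        gene_table, tx_table = dtu_test_all(matrix, tx2gene, meta)
        row = gene_table.set_index("gene_id").loc["G00005"]
        assert bool(row["screened"])
        confirmed = tx_table[(tx_table["gene_id"] == "G00005")
                             & (tx_table["stagewise_adj_p"] < 0.05)]
        assert len(confirmed) >= 1
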
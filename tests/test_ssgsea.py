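"""ssGSEA against a brute-force running-sum oracle, plus rank invariances."""

import numpy as np
import pandas as pd
import pytest

from hypobias.signatures import GeneSignature
from hypobias.ssgsea import SsgseaParams, ssgsea_scores


def running_sum_oracle(values: dict, sig_genes, alpha: float) -> float:
    """Walk the descending-expression list by hand, accumulating the
    weighted in-set ECDF minus the uniform out-of-set ECDF at every step."""
    genes = sorted(values, key=lambda g: values[g], reverse=True)
    n = len(genes)
    m = sum(g in sig_genes for g in genes)
    # average ranks, 1 = lowest expression
    by_val = sorted(values, key=lambda g: values[g])
    rank = {}
    i = 0
    while i < len(by_val):
        j = i
        while j + 1 < len(by_val) and values[by_val[j + 1]] == values[by_val[i]]:
            j += 1
        avg = (i + 1 + j + 1) / 2
        for k in range(i, j + 1):
            rank[by_val[k]] = avg
        i = j + 1
    sum_w = sum(rank[g] ** alpha for g in genes if g in sig_genes)
    cum_in = cum_out = score = 0.0
    for g in genes:
        if g in sig_genes:
            cum_in += rank[g] ** alpha / sum_w
        elif n > m:
            cum_out += 1.0 / (n - m)
        score += cum_in - cum_out
    return score


def frame(values_by_sample, genes):
    return pd.DataFrame(values_by_sample, index=genes)


RAW = SsgseaParams(normalize=False)


def test_five_gene_alpha_zero_enumeration():
    genes = list("ABCDE")
    expr = frame({"s": [5.0, 4.0, 3.0, 2.0, 1.0]}, genes)
    sig = GeneSignature("top2", {"A", "B"})
    score = ssgsea_scores(expr, sig, SsgseaParams(alpha=0.0, normalize=False))
    # hand enumeration: cum_in 1/2,1,1,1,1; cum_out 0,0,1/3,2/3,1
    expected = 0.5 + 1.0 + (1 - 1 / 3) + (1 - 2 / 3) + 0.0
    assert score.loc["s", "top2"] == pytest.approx(expected, abs=1e-12)
    assert score.loc["s", "top2"] == pytest.approx(
        running_sum_oracle({g: v for g, v in zip(genes, expr["s"])}, sig.genes, 0.0)
    )


def test_matches_oracle_on_random_table():
    rng = np.random.default_rng(11)
    genes = [f"G{i:03d}" for i in range(50)]
    expr = frame({f"s{j}": rng.lognormal(size=50) for j in range(8)}, genes)
    sig = GeneSignature("set", rng.choice(genes, size=12, replace=False))
    scores = ssgsea_scores(expr, sig, RAW)
    for s in expr.columns:
        exp = running_sum_oracle(dict(expr[s]), sig.genes, 0.25)
        assert scores.loc[s, "set"] == pytest.approx(exp, abs=1e-9)


def test_whole_universe_identical_across_samples():
    rng = np.random.default_rng(3)
    genes = [f"G{i}" for i in range(20)]
    expr = frame({"a": rng.permutation(20) + 1.0, "b": rng.lognormal(size=20)}, genes)
    sig = GeneSignature("all", genes)
    scores = ssgsea_scores(expr, sig, RAW)
    assert scores.loc["a", "all"] == pytest.approx(scores.loc["b", "all"])


def test_rank_identical_samples_equal_scores():
    genes = [f"G{i}" for i in range(30)]
    base = np.linspace(1, 30, 30)
    expr = frame({"raw": base, "squared": base**2}, genes)
    sig = GeneSignature("s", genes[:7])
    scores = ssgsea_scores(expr, sig, RAW)
    assert scores.loc["raw", "s"] == pytest.approx(scores.loc["squared", "s"])


def test_monotone_transform_invariance():
    rng = np.random.default_rng(9)
    genes = [f"G{i}" for i in range(40)]
    vals = rng.lognormal(size=40)
    sig = GeneSignature("s", rng.choice(genes, size=10, replace=False))
    a = ssgsea_scores(frame({"x": vals}, genes), sig, RAW)
    b = ssgsea_scores(frame({"x": np.exp(vals)}, genes), sig, RAW)
    c = ssgsea_scores(frame({"x": np.log(vals)}, genes), sig, RAW)
    assert a.loc["x", "s"] == pytest.approx(b.loc["x", "s"], abs=1e-9)
    assert a.loc["x", "s"] == pytest.approx(c.loc["x", "s"], abs=1e-9)


def test_complement_negation_alpha_zero():
    rng = np.random.default_rng(21)
    genes = [f"G{i}" for i in range(25)]
    expr = frame({"x": rng.lognormal(size=25)}, genes)
    sig = GeneSignature("s", genes[:9])
    comp = GeneSignature("c", genes[9:])
    p = SsgseaParams(alpha=0.0, normalize=False)
    s = ssgsea_scores(expr, sig, p).loc["x", "s"]
    sc = ssgsea_scores(expr, comp, p).loc["x", "c"]
    assert s == pytest.approx(-sc, abs=1e-9)
    assert s == pytest.approx(
        running_sum_oracle(dict(expr["x"]), sig.genes, 0.0), abs=1e-9
    )


def test_normalization_divides_by_table_range():
    rng = np.random.default_rng(5)
    genes = [f"G{i}" for i in range(30)]
    expr = frame({f"s{j}": rng.lognormal(size=30) for j in range(4)}, genes)
    sigs = [GeneSignature("a", genes[:8]), GeneSignature("b", genes[8:16])]
    raw = ssgsea_scores(expr, sigs, RAW)
    norm = ssgsea_scores(expr, sigs, SsgseaParams())
    rng_ = raw.to_numpy().max() - raw.to_numpy().min()
    np.testing.assert_allclose(norm.to_numpy(), raw.to_numpy() / rng_)


def test_insufficient_overlap_names_signature():
    expr = frame({"s": [1.0, 2.0, 3.0]}, ["A", "B", "C"])
    with pytest.raises(ValueError, match="missing_set"):
        ssgsea_scores(expr, GeneSignature("missing_set", {"X", "Y"}))
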
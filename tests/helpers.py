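"""Shared test utilities: record builders and independent brute-force oracles.

The oracles here deliberately re-state each filtering predicate in plain
Python over dict rows, independent of the vectorized implementation they
check.
"""

from __future__ import annotations

import itertools
import math
import random

import pandas as pd

from pgin.io_formats import VARIANT_COLUMNS, _coerce_schema

_DEFAULTS = {
    "sample_id": "S1",
    "chrom": "1",
    "pos": 100,
    "ref": "C",
    "alt": "T",
    "gene": "GENE1",
    "classification": "missense",
    "variant_type": "SNV",
    "dp": 100,
    "gq": 80.0,
    "qd": 20.0,
    "mq": 55.0,
    "read_pos_rank_sum": 0.0,
    "mq_rank_sum": 0.0,
    "fs": 5.0,
    "qual": 500.0,
    "max_af": 0.001,
    "polyphen": None,
    "sift": None,
    "clinvar_sig": None,
    "alt_count": 50,
    "ref_count": 50,
    "context5": "A",
    "context3": "A",
    "rna_editing_site": False,
    "low_complexity": False,
    "common_variant": False,
}


def make_variant(**overrides) -> dict:
    """A clean passing variant row, overridable field by field."""
    row = dict(_DEFAULTS)
    row.update(overrides)
    return row


def variants_frame(rows: list[dict]) -> pd.DataFrame:
    return _coerce_schema(pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)))


# ---------------------------------------------------------------------------
# Brute-force filter-cascade oracle
# ---------------------------------------------------------------------------

_QUALITY = [
    ("dp", ">", 10),
    ("gq", ">", 20),
    ("qd", ">", 5),
    ("mq", ">", 40),
    ("read_pos_rank_sum", ">", -3),
    ("mq_rank_sum", ">", -10),
    ("fs", "<", 200),
    ("qual", ">", 50),
]


def brute_force_cascade(rows: list[dict], config) -> dict:
    """Evaluate every printed predicate per variant, by index.

    Returns {'rare': set of row indices, 'rare_damaging': set}.
    """

    def quality_ok(r):
        for key, d, t in _QUALITY:
            v = r.get(key)
            if v is None:
                if config.strict_missing_quality:
                    return False
                continue
            if d == ">" and not v > t:
                return False
            if d == "<" and not v < t:
                return False
        return True

    def somatic_ok(r):
        return not (
            bool(r.get("rna_editing_site"))
            or bool(r.get("low_complexity"))
            or bool(r.get("common_variant"))
        )

    n_samples = len({r["sample_id"] for r in rows})
    survivors = [i for i, r in enumerate(rows) if quality_ok(r) and somatic_ok(r)]

    def depth_af_ok(r):
        if r.get("dp") is None or not r["dp"] > config.burden_depth_threshold:
            return False
        af = r.get("max_af")
        if af is None:
            return config.missing_af_is_rare
        return af < config.rare_af_threshold

    candidates = [i for i in survivors if depth_af_ok(rows[i])]

    site_samples: dict[tuple, set] = {}
    gene_samples: dict[str, set] = {}
    for i in candidates:
        r = rows[i]
        site = (r["chrom"], r["pos"], r["ref"], r["alt"])
        site_samples.setdefault(site, set()).add(r["sample_id"])
        gene_samples.setdefault(r["gene"], set()).add(r["sample_id"])

    rare = set()
    for i in candidates:
        r = rows[i]
        site = (r["chrom"], r["pos"], r["ref"], r["alt"])
        if len(site_samples[site]) / n_samples > config.variant_recurrence_max:
            continue
        if len(gene_samples[r["gene"]]) / n_samples > config.gene_recurrence_max:
            continue
        rare.add(i)

    def damaging_ok(r):
        pp = r.get("polyphen") == "damaging"
        sf = r.get("sift") == "deleterious"
        trunc = r.get("classification") in ("nonsense", "nonstop")
        if r.get("clinvar_sig") == "benign":
            return False
        if config.damaging_rule == "union":
            return pp or sf or trunc
        return (pp and sf) or trunc

    return {"rare": rare, "rare_damaging": {i for i in rare if damaging_ok(rows[i])}}


def random_cascade_fixture(rng: random.Random, n: int) -> list[dict]:
    """Random variant rows rich in boundary values and recurrent sites."""
    samples = [f"S{i}" for i in range(6)]
    sites = [("1", 100 + j, "C", "T") for j in range(12)]
    genes = [f"G{j}" for j in range(6)]
    rows = []
    for _ in range(n):
        chrom, pos, ref, alt = rng.choice(sites)
        row = make_variant(
            sample_id=rng.choice(samples),
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=rng.choice(genes),
            dp=rng.choice([None, 5, 9, 10, 11, 30, 31, 50, 51, 120]),
            gq=rng.choice([None, 19.0, 20.0, 21.0, 90.0]),
            qd=rng.choice([None, 4.9, 5.0, 5.1, 25.0]),
            mq=rng.choice([None, 39.0, 40.0, 41.0, 60.0]),
            read_pos_rank_sum=rng.choice([None, -3.1, -3.0, -2.9, 0.0]),
            mq_rank_sum=rng.choice([None, -10.5, -10.0, -9.9, 0.0]),
            fs=rng.choice([None, 199.0, 200.0, 201.0, 3.0]),
            qual=rng.choice([None, 49.0, 50.0, 51.0, 800.0]),
            max_af=rng.choice([None, 0.0, 0.0099, 0.01, 0.011, 0.2]),
            polyphen=rng.choice([None, "damaging", "possibly_damaging", "benign"]),
            sift=rng.choice([None, "deleterious", "tolerated"]),
            clinvar_sig=rng.choice([None, "benign", "other"]),
            classification=rng.choice(
                ["missense", "nonsense", "nonstop", "silent", "splice", "other"]
            ),
            rna_editing_site=rng.random() < 0.1,
            low_complexity=rng.random() < 0.05,
            common_variant=rng.random() < 0.1,
        )
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Exact-test enumeration oracles
# ---------------------------------------------------------------------------


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over the table's
    support: sum of probabilities of all tables (same margins) no more
    probable than the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def mannwhitney_p_enumeration(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments
    (tie-free data): p = 2 * min(P(U <= u), P(U >= u)), capped at 1."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    m, n = len(x), len(y)
    all_vals = sorted(pooled)

    def u_stat(xs):
        return sum(1 for xi in xs for yj in set(all_vals) - set(xs) if xi > yj)

    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = [
        sum(1 for xi in combo for yj in (set(all_vals) - set(combo)) if xi > yj)
        for combo in itertools.combinations(all_vals, m)
    ]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def bh_step_up(pvals) -> list:
    """Hand application of the Benjamini-Hochberg step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def auc_by_pair_counting(y, scores) -> float:
    """AUC as the scaled Mann-Whitney U with half credit for ties."""
    pos = [s for yi, s in zip(y, scores) if yi == 1]
    neg = [s for yi, s in zip(y, scores) if yi == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
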
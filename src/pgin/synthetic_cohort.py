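"""Synthetic cohort generator with planted, recoverable parameters.

Emulates the structure of a placental bulk RNA-seq study: an annotated
somatic variant table, per-sample genome-coverage histograms, a gene x
sample expression matrix, and cohort metadata with gestational age at
delivery and PE / MVM / SGA outcome flags. Every generative parameter is
recorded in a truth object so that each downstream stage has a recovery
test: filter pass fractions, the per-group signature mixtures, the
expression up-shift on hypoxia genes, and the log hazard ratios of the
gestational-age-to-event model.

Two labelling schemes are supported. ``group_counts`` (the default,
23 / 30 / 20 / 39 over EP-N, NTT-N, EP-PE, NTT-PE at n=112) fixes the
group sizes exactly and draws delivery times inside each group's
gestational-age window; passing ``group_counts=None`` instead draws event
times freely from the proportional-hazards model, which is the mode used
for hazard-ratio recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .hypoxia import GeneSignature
from .io_formats import CoverageProfile, write_coverage, write_variant_table
from .signatures import CHANNELS, MutationCatalog, SignatureSet, read_reference_signatures

GROUPS = ("EP-N", "NTT-N", "EP-PE", "NTT-PE")

#: per-group exposure over (SBS1, SBS5, SBS18, SBS34) analogs; EP-PE is
#: dominated by the oxidative C>A shape with a minor T>A component, EP-N by
#: the flat clock-like background, the near-term groups by a clock +
#: oxidative blend.
DEFAULT_MIXTURES: dict[str, tuple[float, ...]] = {
    "EP-N": (0.15, 0.65, 0.15, 0.05),
    "NTT-N": (0.40, 0.15, 0.40, 0.05),
    "EP-PE": (0.10, 0.15, 0.60, 0.15),
    "NTT-PE": (0.35, 0.20, 0.40, 0.05),
}


@dataclass
class SimulationSpec:
    """Planted parameters of one synthetic cohort."""

    n_samples: int = 112
    seed: int = 0
    mean_variants_per_sample: float = 120.0
    frac_rare: float = 0.40
    frac_damaging_of_rare: float = 0.25
    covered_mb_range: tuple[float, float] = (30.0, 60.0)
    signature_mixture: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURES)
    )
    mutations_per_catalog: int | None = None  # None: one context per simulated SNV
    hypoxia_shift: float = 1.0  # log-expression up-shift per unit hypoxia latent
    n_hypoxia_genes_per_set: int = 10
    n_background_genes: int = 150
    true_log_hr_instability: float = math.log(1.7)
    true_log_hr_hypoxia: float = math.log(1.3)
    censor_week_min: float = 20.0
    censor_week_max: float = 42.0
    baseline_hazard: float = 0.04  # events per week past censor_week_min
    group_counts: dict[str, int] | None = field(
        default_factory=lambda: {"EP-N": 23, "NTT-N": 30, "EP-PE": 20, "NTT-PE": 39}
    )
    # latent shifts that plant the observed group contrasts
    instability_shift_eppe: float = 1.4  # ~1.75x variant rate in EP-PE
    hypoxia_group_shift: float = 1.0
    clock_burden_coupling: float = 0.4  # mixture drift toward the clock analog with burden

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ParameterError("n_samples must be >= 2")
        for name in ("frac_rare", "frac_damaging_of_rare"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for g, mix in self.signature_mixture.items():
            if not math.isclose(sum(mix), 1.0, abs_tol=1e-9):
                raise ParameterError(f"signature mixture for {g} must sum to 1")
        if self.group_counts is not None and sum(self.group_counts.values()) != self.n_samples:
            raise ParameterError("group_counts must sum to n_samples")
        if self.covered_mb_range[0] <= 0 or self.covered_mb_range[0] > self.covered_mb_range[1]:
            raise ParameterError("covered_mb_range must be a positive interval")


@dataclass
class CohortBundle:
    """Everything one pipeline run consumes, plus the generative truth."""

    variants: pd.DataFrame
    coverage: dict[str, CoverageProfile]
    expression: pd.DataFrame
    metadata: pd.DataFrame
    hypoxia_signatures: list[GeneSignature]
    truth: dict


def simulate_catalog(
    mixture,
    n_mutations: int,
    reference: SignatureSet,
    seed: int,
) -> np.ndarray:
    """One catalog column: a multinomial draw from the mixed channel
    distribution ``mixture @ reference.signatures``."""
    mixture = np.asarray(mixture, dtype=float)
    if mixture.shape != (reference.signatures.shape[0],):
        raise ParameterError(
            f"mixture length {mixture.shape} != number of reference signatures "
            f"{reference.signatures.shape[0]}"
        )
    if not math.isclose(mixture.sum(), 1.0, abs_tol=1e-9):
        raise ParameterError("mixture must sum to 1")
    probs = mixture @ reference.signatures
    rng = np.random.default_rng(seed)
    return rng.multinomial(int(n_mutations), probs)


def simulate_cohort_catalog(
    mixtures: np.ndarray, n_mutations: int, reference: SignatureSet, seed: int
) -> MutationCatalog:
    """Catalog with one column per row of ``mixtures`` (known exposures)."""
    ss = np.random.SeedSequence(seed).spawn(len(mixtures))
    cols = [
        simulate_catalog(m, n_mutations, reference, s.generate_state(1)[0] % 2**31)
        for m, s in zip(mixtures, ss)
    ]
    sample_ids = [f"SIM{i:03d}" for i in range(len(mixtures))]
    return MutationCatalog(counts=np.column_stack(cols), sample_ids=sample_ids)


def _truncated_shifted_exp(rng, lam: float, lo: float, hi: float, t0: float) -> float:
    """Draw from hazard-rate ``lam`` past week ``t0``, truncated to (lo, hi]."""
    a, b = max(lo, t0) - t0, hi - t0
    u = rng.uniform()
    mass = math.exp(-lam * a) - math.exp(-lam * b)
    return t0 - math.log(math.exp(-lam * a) - u * mass) / lam


def _decode_channel(channel: str) -> tuple[str, str, str, str]:
    c5, rest = channel[0], channel[2:-2]
    ref, alt = rest.split(">")
    return c5, ref, alt, channel[-1]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_cohort(spec: SimulationSpec, reference: SignatureSet | None = None) -> CohortBundle:
    """Generate a full cohort bundle; byte-reproducible from ``spec.seed``."""
    if reference is None:
        reference = read_reference_signatures()
    root = np.random.SeedSequence(spec.seed)
    rng_groups, rng_var, rng_cov, rng_expr, rng_surv = (
        np.random.default_rng(s) for s in root.spawn(5)
    )
    n = spec.n_samples
    sample_ids = [f"P{i:04d}" for i in range(n)]

    # --- latent covariates and outcome labels -----------------------------
    z_inst = rng_groups.normal(0.0, 1.0, n)
    z_hyp = rng_groups.normal(0.0, 1.0, n)
    if spec.group_counts is not None:
        groups = np.repeat(
            [g for g in GROUPS if g in spec.group_counts],
            [spec.group_counts[g] for g in GROUPS if g in spec.group_counts],
        )
        perm = rng_groups.permutation(n)
        groups = groups[perm]
        pe = np.array([g.endswith("PE") for g in groups])
        # plant the observed contrasts: EP-PE has higher instability, every
        # group except NTT-N has a higher hypoxia latent
        z_inst = z_inst + spec.instability_shift_eppe * (groups == "EP-PE")
        z_hyp = z_hyp + spec.hypoxia_group_shift * (groups != "NTT-N")
        lam = spec.baseline_hazard * np.exp(
            spec.true_log_hr_instability * z_inst + spec.true_log_hr_hypoxia * z_hyp
        )
        # windows keep a 0.01-week margin so rounding cannot cross the
        # 34-week early-preterm boundary
        ga = np.empty(n)
        for i in range(n):
            if pe[i]:
                lo, hi = (
                    (spec.censor_week_min, 33.99)
                    if groups[i].startswith("EP")
                    else (34.01, spec.censor_week_max)
                )
                ga[i] = _truncated_shifted_exp(rng_surv, lam[i], lo, hi, spec.censor_week_min)
            else:
                lo, hi = (24.0, 33.99) if groups[i].startswith("EP") else (34.01, 41.5)
                ga[i] = rng_surv.uniform(lo, hi)
    else:
        lam = spec.baseline_hazard * np.exp(
            spec.true_log_hr_instability * z_inst + spec.true_log_hr_hypoxia * z_hyp
        )
        t = spec.censor_week_min + rng_surv.exponential(1.0 / lam)
        pe = t <= spec.censor_week_max
        ga = np.minimum(t, spec.censor_week_max)
        groups = np.where(ga < 34.0, "EP", "NTT").astype(object)
        groups = np.array(
            [f"{g}-PE" if e else f"{g}-N" for g, e in zip(groups, pe)], dtype=object
        )

    mvm = np.where(pe, rng_groups.uniform(size=n) < 0.47, rng_groups.uniform(size=n) < 0.19)
    sga = np.where(pe, rng_groups.uniform(size=n) < 0.76, rng_groups.uniform(size=n) < 0.05)
    fetal_sex = np.where(rng_groups.uniform(size=n) < 0.5, "female", "male")
    maternal_age = np.clip(rng_groups.normal(31.0, 5.0, n), 18.0, 45.0).round(1)

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "ga_weeks": np.round(ga, 2),
            "pe": pe,
            "mvm": mvm,
            "sga": sga,
            "fetal_sex": fetal_sex,
            "maternal_age": maternal_age,
            "group": groups,
        }
    )

    # --- coverage histograms ---------------------------------------------
    coverage: dict[str, CoverageProfile] = {}
    covered_bases = np.empty(n, dtype=int)
    for i, sid in enumerate(sample_ids):
        target = int(rng_cov.uniform(*spec.covered_mb_range) * 1e6)
        covered_bases[i] = target
        depths = np.unique(50 + rng_cov.poisson(60, 25))
        weights = rng_cov.dirichlet(np.ones(len(depths)))
        hist = {int(d): int(c) for d, c in zip(depths, rng_cov.multinomial(target, weights)) if c > 0}
        low_total = int(0.5 * target)
        low_depths = np.unique(rng_cov.integers(1, 50, 12))
        low_w = rng_cov.dirichlet(np.ones(len(low_depths)))
        for d, c in zip(low_depths, rng_cov.multinomial(low_total, low_w)):
            if c > 0:
                hist[int(d)] = hist.get(int(d), 0) + int(c)
        hist[0] = int(3.1e9) - sum(hist.values())
        coverage[sid] = CoverageProfile(sample_id=sid, depth_hist=hist)

    # --- variant table ----------------------------------------------------
    mixture_rows = {g: np.asarray(spec.signature_mixture.get(g, next(iter(spec.signature_mixture.values())))) for g in set(groups)}
    # detected variants scale with both the latent instability and the
    # sample's covered megabases, so burden (count / Mb) tracks the latent
    mean_mb = float(np.mean(spec.covered_mb_range))
    rate = (
        spec.mean_variants_per_sample
        * np.exp(0.4 * (z_inst - z_inst.mean()))
        * covered_bases
        / (mean_mb * 1e6)
    )
    gene_pool = [f"GENE{i:04d}" for i in range(3000)]
    chroms = [str(c) for c in range(1, 23)] + ["X"]
    rows: list[dict] = []
    hot_variant = ("1", 555_555, "A", "G")  # planted hotspot to exercise recurrence
    hot_gene = "HOTGENE"
    from scipy.special import expit

    clock = np.zeros(reference.signatures.shape[0])
    clock[0] = 1.0
    for i, sid in enumerate(sample_ids):
        n_var = rng_var.poisson(rate[i])
        # unstable samples drift toward the clock-like analog, planting a
        # positive contribution-vs-burden rank correlation
        c = spec.clock_burden_coupling * float(expit(z_inst[i]))
        mix_i = (1.0 - c) * mixture_rows[groups[i]] + c * clock
        channel_probs = mix_i @ reference.signatures
        for _ in range(n_var):
            vt = rng_var.choice(["SNV", "INS", "DEL"], p=[0.88, 0.06, 0.06])
            row: dict[str, object] = {
                "sample_id": sid,
                "chrom": str(rng_var.choice(chroms)),
                "pos": int(rng_var.integers(10_000, 240_000_000)),
                "gene": str(rng_var.choice(gene_pool)),
            }
            if vt == "SNV":
                ch = CHANNELS[int(rng_var.choice(96, p=channel_probs))]
                c5, ref, alt, c3 = _decode_channel(ch)
                if rng_var.uniform() < 0.5:  # report on the purine strand
                    ref, alt = _COMP[ref], _COMP[alt]
                    c5, c3 = _COMP[c3], _COMP[c5]
                row.update(ref=ref, alt=alt, context5=c5, context3=c3, variant_type="SNV")
            elif vt == "INS":
                ref = str(rng_var.choice(list("ACGT")))
                ins = "".join(rng_var.choice(list("ACGT"), size=int(rng_var.integers(1, 4))))
                row.update(ref=ref, alt=ref + ins, context5=None, context3=None, variant_type="INS")
            else:
                ref = "".join(rng_var.choice(list("ACGT"), size=int(rng_var.integers(2, 5))))
                row.update(ref=ref, alt=ref[0], context5=None, context3=None, variant_type="DEL")

            # quality metrics: a known small fraction fails each threshold
            row["dp"] = int(
                rng_var.integers(1, 11)
                if rng_var.uniform() < 0.04
                else (rng_var.integers(11, 51) if rng_var.uniform() < 0.15 else rng_var.integers(51, 400))
            )
            row["gq"] = float(rng_var.uniform(0, 20) if rng_var.uniform() < 0.03 else rng_var.uniform(25, 99))
            row["qd"] = float(rng_var.uniform(0, 5) if rng_var.uniform() < 0.03 else rng_var.uniform(6, 35))
            row["mq"] = float(rng_var.uniform(20, 40) if rng_var.uniform() < 0.03 else rng_var.uniform(41, 60))
            row["read_pos_rank_sum"] = (
                None if rng_var.uniform() < 0.2 else float(rng_var.normal(0, 1.2))
            )
            row["mq_rank_sum"] = None if rng_var.uniform() < 0.2 else float(rng_var.normal(0, 2.0))
            row["fs"] = float(rng_var.uniform(200, 400) if rng_var.uniform() < 0.02 else rng_var.uniform(0, 60))
            row["qual"] = float(rng_var.uniform(0, 50) if rng_var.uniform() < 0.03 else rng_var.uniform(60, 3000))

            row["rna_editing_site"] = bool(rng_var.uniform() < 0.05)
            row["low_complexity"] = bool(rng_var.uniform() < 0.03)
            row["common_variant"] = bool(rng_var.uniform() < 0.05)

            if rng_var.uniform() < spec.frac_rare:
                row["max_af"] = None if rng_var.uniform() < 0.25 else float(rng_var.uniform(0, 0.0099))
                is_rare = True
            else:
                row["max_af"] = float(rng_var.uniform(0.01, 0.5))
                is_rare = False

            if is_rare and rng_var.uniform() < spec.frac_damaging_of_rare:
                if rng_var.uniform() < 0.3:
                    row["classification"] = "nonsense" if rng_var.uniform() < 0.9 else "nonstop"
                    row["polyphen"], row["sift"] = None, None
                else:
                    row["classification"] = "missense"
                    row["polyphen"] = "damaging"
                    row["sift"] = "deleterious" if rng_var.uniform() < 0.8 else None
            else:
                row["classification"] = str(
                    rng_var.choice(["missense", "silent", "splice", "other"], p=[0.5, 0.3, 0.1, 0.1])
                )
                row["polyphen"] = str(rng_var.choice(["benign", "possibly_damaging"])) if rng_var.uniform() < 0.6 else None
                row["sift"] = "tolerated" if rng_var.uniform() < 0.6 else None
            row["clinvar_sig"] = (
                "benign" if rng_var.uniform() < 0.05 else ("other" if rng_var.uniform() < 0.2 else None)
            )

            vaf = rng_var.beta(2.0, 2.0)
            row["alt_count"] = int(round(vaf * row["dp"]))
            row["ref_count"] = int(row["dp"]) - int(row["alt_count"])
            rows.append(row)

        # planted recurrent sites (always clean-quality, rare-AF)
        if rng_var.uniform() < 0.80:
            rows.append(_hot_row(sid, hot_variant, "RECGENE", rng_var))
        if rng_var.uniform() < 0.60:
            c, p0, r, a = "2", int(7_777_000 + rng_var.integers(0, 5)), "C", "T"
            rows.append(_hot_row(sid, (c, p0, r, a), hot_gene, rng_var))

    variants = pd.DataFrame(rows)
    from .io_formats import _coerce_schema  # shared schema coercion

    variants = _coerce_schema(variants)

    # --- expression matrix ------------------------------------------------
    hyp_sets = [
        GeneSignature(
            name=f"HYPOXIA_{s}",
            genes=[f"{s}HX{j:02d}" for j in range(1, spec.n_hypoxia_genes_per_set + 1)],
        )
        for s in "ABC"
    ]
    hyp_genes = [g for sig in hyp_sets for g in sig.genes]
    bg_genes = [f"BG{j:04d}" for j in range(spec.n_background_genes)]
    genes = hyp_genes + bg_genes
    base = rng_expr.uniform(2.0, 10.0, len(genes))
    expr = base[:, None] + rng_expr.normal(0.0, 0.7, (len(genes), n))
    expr[: len(hyp_genes), :] += spec.hypoxia_shift * z_hyp[None, :]
    expression = pd.DataFrame(np.round(expr, 4), index=genes, columns=sample_ids)
    expression.index.name = "gene"

    truth = {
        "spec": spec,
        "per_sample": pd.DataFrame(
            {
                "sample_id": sample_ids,
                "z_instability": z_inst,
                "z_hypoxia": z_hyp,
                "variant_rate": rate,
                "covered_bases": covered_bases,
                "group": groups,
            }
        ).set_index("sample_id"),
        "log_hr_instability": spec.true_log_hr_instability,
        "log_hr_hypoxia": spec.true_log_hr_hypoxia,
        "mixtures": {g: list(map(float, m)) for g, m in mixture_rows.items()},
        "reference_labels": list(reference.labels),
    }
    return CohortBundle(
        variants=variants,
        coverage=coverage,
        expression=expression,
        metadata=metadata,
        hypoxia_signatures=hyp_sets,
        truth=truth,
    )


def _hot_row(sid: str, site: tuple[str, int, str, str], gene: str, rng) -> dict:
    c, p, ref, alt = site
    dp = int(rng.integers(60, 300))
    alt_count = int(round(0.5 * dp))
    return {
        "sample_id": sid,
        "chrom": c,
        "pos": p,
        "ref": ref,
        "alt": alt,
        "gene": gene,
        "classification": "missense",
        "variant_type": "SNV",
        "dp": dp,
        "gq": 80.0,
        "qd": 20.0,
        "mq": 55.0,
        "read_pos_rank_sum": 0.0,
        "mq_rank_sum": 0.0,
        "fs": 5.0,
        "qual": 500.0,
        "max_af": 0.001,
        "polyphen": "damaging",
        "sift": "deleterious",
        "clinvar_sig": None,
        "alt_count": alt_count,
        "ref_count": dp - alt_count,
        "context5": "A",
        "context3": "A",
        "rna_editing_site": False,
        "low_complexity": False,
        "common_variant": False,
    }


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Write the four input files plus the planted-truth tables."""
    out = Path(out_dir)
    (out / "coverage").mkdir(parents=True, exist_ok=True)
    write_variant_table(bundle.variants, out / "variants.tsv")
    for sid, prof in bundle.coverage.items():
        write_coverage(prof, out / "coverage" / f"{sid}.tsv")
    bundle.expression.to_csv(out / "expression.tsv", sep="\t")
    bundle.metadata.to_csv(out / "metadata.csv", index=False)
    with open(out / "hypoxia_signatures.tsv", "w") as fh:
        for sig in bundle.hypoxia_signatures:
            for g in sig.genes:
                fh.write(f"{sig.name}\t{g}\n")
    bundle.truth["per_sample"].to_csv(out / "truth_samples.tsv", sep="\t")
    with open(out / "truth_params.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"log_hr_instability\t{bundle.truth['log_hr_instability']}\n")
        fh.write(f"log_hr_hypoxia\t{bundle.truth['log_hr_hypoxia']}\n")
        for g, m in sorted(bundle.truth["mixtures"].items()):
            fh.write(f"mixture_{g}\t{','.join(f'{x:g}' for x in m)}\n")
        fh.write(f"reference_labels\t{','.join(bundle.truth['reference_labels'])}\n")
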
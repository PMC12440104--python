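"""Single-base-substitution (SBS) mutational signatures.

Catalogs are 96-channel trinucleotide-context count matrices in the
standard COSMIC channel order: the six pyrimidine-centred substitution
classes C>A, C>G, C>T, T>A, T>C, T>G, each expanded over the sixteen
flanking-base pairs with both flanks in alphabetical order (A, C, G, T).
Purine-reference calls are folded onto the pyrimidine strand by reverse
complement. De-novo signatures are extracted by non-negative matrix
factorization under the Frobenius objective and matched to a reference
catalog by cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import NMF

from .exceptions import (
    ChannelOrderError,
    DegenerateInputError,
    FormatError,
    ParameterError,
)

logger = logging.getLogger("pgin")

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: the 96 channels in COSMIC order (substitution-major, flanks alphabetical)
CHANNELS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in BASES for f3 in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MutationCatalog:
    """96 x n_samples SNV count matrix."""

    counts: np.ndarray
    sample_ids: list[str]
    contexts: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96, len(self.sample_ids)):
            raise ParameterError(
                f"catalog shape {self.counts.shape} != (96, {len(self.sample_ids)})"
            )
        if (self.counts < 0).any():
            raise ParameterError("catalog counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.contexts), columns=self.sample_ids)


@dataclass
class SignatureSet:
    """Extracted (or reference) signatures with optional exposures."""

    signatures: np.ndarray  # K x 96 probability vectors
    labels: list[str]
    exposures: np.ndarray | None = None  # n_samples x K
    sample_ids: list[str] | None = None
    contexts: tuple[str, ...] = CHANNELS
    reference_matches: list[tuple[str, float]] | None = None
    reconstruction_error: float | None = None

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        if self.signatures.ndim != 2 or self.signatures.shape[1] != 96:
            raise ParameterError("signatures must be K x 96")
        sums = self.signatures.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ParameterError("each signature must sum to 1 within 1e-9")
        if self.exposures is not None and (np.asarray(self.exposures) < 0).any():
            raise ParameterError("exposures must be non-negative")


# ---------------------------------------------------------------------------
# Catalog construction
# ---------------------------------------------------------------------------


def reverse_complement_channel(ref: str, alt: str, c5: str, c3: str) -> tuple[str, str, str, str]:
    """Fold a purine-reference SNV onto the pyrimidine strand.

    Ref, alt and both flanks are complemented and the flanks swap sides.
    """
    return _COMPLEMENT[ref], _COMPLEMENT[alt], _COMPLEMENT[c3], _COMPLEMENT[c5]


def snv_channel(ref: str, alt: str, c5: str, c3: str) -> str:
    """Channel label for one SNV, folding to the pyrimidine strand."""
    for b in (ref, alt, c5, c3):
        if b not in _COMPLEMENT:
            raise FormatError(f"non-ACGT base in SNV context: {ref}>{alt} [{c5},{c3}]")
    if ref in ("A", "G"):
        ref, alt, c5, c3 = reverse_complement_channel(ref, alt, c5, c3)
    return f"{c5}[{ref}>{alt}]{c3}"


def build_catalog(variants: pd.DataFrame, sample_ids: list[str] | None = None) -> MutationCatalog:
    """Count SNVs into the 96-channel catalog, one column per sample.

    SNVs missing either flank are dropped (count logged); a non-ACGT base
    raises a row-level error. Non-SNV records are ignored.
    """
    snvs = variants[variants["variant_type"] == "SNV"]
    if sample_ids is None:
        sample_ids = sorted(snvs["sample_id"].dropna().unique())
    col_of = {s: j for j, s in enumerate(sample_ids)}
    counts = np.zeros((96, len(sample_ids)), dtype=int)
    n_dropped = 0
    for row in snvs.itertuples(index=True):
        if pd.isna(row.context5) or pd.isna(row.context3):
            n_dropped += 1
            continue
        try:
            channel = snv_channel(str(row.ref), str(row.alt), str(row.context5), str(row.context3))
        except FormatError as exc:
            raise FormatError(f"row {row.Index}: {exc}") from exc
        j = col_of.get(row.sample_id)
        if j is not None:
            counts[_CHANNEL_INDEX[channel], j] += 1
    if n_dropped:
        logger.info("build_catalog: dropped %d SNVs lacking flanking context", n_dropped)
    return MutationCatalog(counts=counts, sample_ids=list(sample_ids))


# ---------------------------------------------------------------------------
# NMF extraction and reference matching
# ---------------------------------------------------------------------------


def extract_signatures(
    catalog: MutationCatalog,
    rank: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-6,
) -> SignatureSet:
    """Factorize the catalog into ``rank`` signatures and exposures.

    Multiplicative-update NMF under the Frobenius objective, best of
    ``n_restarts`` random initializations; signatures are normalized to
    probability vectors with exposures rescaled to compensate, and ordered
    by total exposure (labels SBSA, SBSB, ...). Deterministic given seed.
    """
    X = np.asarray(catalog.counts, dtype=float)
    n_samples = X.shape[1]
    if not (2 <= rank <= min(96, n_samples)) and rank != 1:
        raise ParameterError(f"rank must be in [1, min(96, n_samples)]; got {rank}")
    if X.sum() <= 0:
        raise DegenerateInputError("catalog has zero total count; nothing to factorize")

    rng_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for rs in rng_seeds:
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=int(rs % (2**31)),
        )
        W = model.fit_transform(X)  # 96 x K
        H = model.components_  # K x n_samples
        err = float(model.reconstruction_err_)
        if best is None or err < best[0]:
            best = (err, W, H)
    err, W, H = best
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    sigs = (W / colsum).T  # K x 96
    expo = (H * colsum[:, None]).T  # n_samples x K
    order = np.argsort(-expo.sum(axis=0), kind="stable")
    sigs, expo = sigs[order], expo[:, order]
    # guard against round-off in the probability normalization
    sigs = sigs / sigs.sum(axis=1, keepdims=True)
    labels = [f"SBS{chr(ord('A') + k)}" for k in range(rank)]
    return SignatureSet(
        signatures=sigs,
        labels=labels,
        exposures=expo,
        sample_ids=list(catalog.sample_ids),
        reconstruction_error=err,
    )


def cosine_similarity_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows of ``a`` and rows of ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (a / na) @ (b / nb).T


def match_to_reference(signatures: SignatureSet, reference: SignatureSet) -> list[tuple[str, float]]:
    """Best-cosine reference signature for each extracted one.

    Ties go to the earlier reference in file order. Channel orders must
    agree exactly.
    """
    if tuple(signatures.contexts) != tuple(reference.contexts):
        raise ChannelOrderError("extracted and reference catalogs disagree on channel order")
    sims = cosine_similarity_matrix(signatures.signatures, reference.signatures)
    matches = []
    for i in range(sims.shape[0]):
        j = int(np.argmax(sims[i]))  # argmax returns the first maximum
        matches.append((reference.labels[j], float(sims[i, j])))
    signatures.reference_matches = matches
    return matches


def group_contributions(
    signature_set: SignatureSet, metadata: pd.DataFrame, grouping: str
) -> pd.DataFrame:
    """Mean relative signature contribution per outcome group.

    Per-sample exposures are normalized to sum to one (zero-exposure
    samples are excluded and logged) and averaged within each level of
    ``metadata[grouping]``.
    """
    if signature_set.exposures is None or signature_set.sample_ids is None:
        raise ParameterError("signature set carries no exposures")
    expo = pd.DataFrame(
        signature_set.exposures, index=signature_set.sample_ids, columns=signature_set.labels
    )
    totals = expo.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.info("group_contributions: excluding %d zero-exposure samples", int(zero.sum()))
    rel = expo[~zero].div(totals[~zero], axis=0)
    groups = metadata.loc[rel.index, grouping]
    out = {}
    for g in pd.unique(metadata[grouping].dropna()):
        members = rel[groups == g]
        if members.empty:
            logger.warning("group_contributions: group %r has no usable samples; skipped", g)
            continue
        out[g] = members.mean(axis=0)
    return pd.DataFrame(out).T


def correlate_contribution_burden(
    signature_set: SignatureSet,
    burden: pd.Series,
    label: str | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation between a signature's relative
    contribution and genomic instability, with two-sided p.

    ``label`` defaults to the first (largest-exposure) signature.
    """
    if signature_set.exposures is None or signature_set.sample_ids is None:
        raise ParameterError("signature set carries no exposures")
    label = label or signature_set.labels[0]
    k = signature_set.labels.index(label)
    expo = pd.DataFrame(
        signature_set.exposures, index=signature_set.sample_ids, columns=signature_set.labels
    )
    totals = expo.sum(axis=1)
    rel = (expo[label] / totals.replace(0, np.nan)).dropna()
    common = rel.index.intersection(burden.dropna().index)
    if len(common) < 3:
        raise ParameterError("need at least 3 samples with contribution and burden")
    x = rel.loc[common].to_numpy(float)
    y = burden.loc[common].to_numpy(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant input; rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    tie_free = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    if len(x) <= 8 and tie_free:
        # exact two-sided p by permutation enumeration (t-approximation is
        # unreliable at these sizes)
        from itertools import permutations

        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx = rx - rx.mean()
        denom = np.sqrt((rx**2).sum())
        count = total = 0
        for perm in permutations(ry):
            r = float(rx @ (np.asarray(perm) - ry.mean())) / (denom**2)
            total += 1
            count += abs(r) >= abs(rho) - 1e-12
        p = count / total
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Reference catalog I/O
# ---------------------------------------------------------------------------


def read_reference_signatures(path: str | Path | None = None) -> SignatureSet:
    """Load a reference signature TSV (channel column + one column per
    signature). Defaults to the packaged synthetic reference analogs."""
    if path is None:
        path = resources.files("pgin.data") / "synthetic_sbs_reference.tsv"
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if list(df.index) != list(CHANNELS):
        raise ChannelOrderError(f"{path}: channels are not in the expected 96-channel order")
    mat = df.to_numpy(float).T
    mat = mat / mat.sum(axis=1, keepdims=True)
    return SignatureSet(signatures=mat, labels=list(df.columns))


def write_signature_set(sigset: SignatureSet, path: str | Path) -> None:
    pd.DataFrame(sigset.signatures.T, index=list(sigset.contexts), columns=sigset.labels).to_csv(
        path, sep="\t", index_label="channel"
    )


def write_exposures(sigset: SignatureSet, path: str | Path) -> None:
    if sigset.exposures is None:
        raise ParameterError("signature set carries no exposures")
    pd.DataFrame(sigset.exposures, index=sigset.sample_ids, columns=sigset.labels).to_csv(
        path, sep="\t", index_label="sample_id"
    )
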
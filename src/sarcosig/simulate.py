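"""Synthetic cohorts with known ground truth.

Expression cohorts are simulated on the log2 scale: a fixed per-gene
baseline, an additive signed shift on the signature genes of chosen
subtypes, and i.i.d. Gaussian noise.  Companion generators produce qPCR Ct
plates (standard dilution series + samples with planted copy numbers) and
FISH per-cell count tables.  A single seed governs all draws; every
operation derives its own sub-stream deterministically, so identical
configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import GeneSignature

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "simulate_expression",
    "random_signature",
    "simulate_qpcr",
    "simulate_fish_cells",
]


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated expression cohort.

    ``planted_effects`` lists (signature_name, subtype_label, delta)
    triples: samples of that subtype get ``direction(g) * delta`` added to
    every gene g of the named signature.
    """

    n_genes: int
    subtypes: Sequence[tuple[str, int]]
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    noise_sd: float = 1.0
    planted_effects: Sequence[tuple[str, str, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        labels = [lab for lab, _ in self.subtypes]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate subtype labels: {labels}")
        if any(n < 1 for _, n in self.subtypes):
            raise ValueError("all subtype sample counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        for sig_name, label, _ in self.planted_effects:
            if label not in labels:
                raise ValueError(
                    f"planted effect on unknown subtype {label!r} "
                    f"(signature {sig_name!r})"
                )


@dataclass
class GroundTruth:
    """What was planted: baselines, shifts and signature membership."""

    baseline: pd.Series  # gene -> baseline log2 expression
    planted: pd.DataFrame  # columns gene, subtype, shift (signed)
    membership: pd.DataFrame  # columns gene, signature, direction

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "baseline": {g: float(v) for g, v in self.baseline.items()},
                "planted": self.planted.to_dict(orient="records"),
                "membership": self.membership.to_dict(orient="records"),
            },
            indent=2,
            sort_keys=True,
        )


def _sub_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_expression(
    config: CohortConfig, signatures: Iterable[GeneSignature] = ()
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a log2 expression cohort with planted signature effects.

    Returns the genes x samples matrix, a sample -> subtype annotation
    Series and the ground truth.  The gene universe consists of ``n_genes``
    synthetic genes (G0001, ...); signature genes not already in the
    universe are appended so planted effects are always realizable.

    Model: ``value(g, s) = baseline(g) + direction(g) * delta`` for every
    planted (signature, subtype) pair with g in the signature and s in the
    subtype, plus Gaussian noise of sd ``noise_sd``.
    """
    signatures = list(signatures)
    by_name = {s.name: s for s in signatures}
    for sig_name, _, _ in config.planted_effects:
        if sig_name not in by_name:
            raise ValueError(f"planted effect names unknown signature {sig_name!r}")

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    seen = set(genes)
    for sig in signatures:
        for g in sorted(sig.genes):
            if g not in seen:
                genes.append(g)
                seen.add(g)

    sample_ids: list[str] = []
    sample_subtype: list[str] = []
    for label, n in config.subtypes:
        for i in range(n):
            sample_ids.append(f"{label}_{i + 1:04d}")
            sample_subtype.append(label)
    annotation = pd.Series(sample_subtype, index=pd.Index(sample_ids,
                           name="sample_id"), name="subtype")

    rng_base, rng_noise = _sub_rngs(config.seed, 2)
    baseline = pd.Series(
        config.baseline_mean
        + config.baseline_sd * rng_base.standard_normal(len(genes)),
        index=pd.Index(genes, name="gene_id"),
        name="baseline",
    )
    values = baseline.to_numpy()[:, None] + config.noise_sd * (
        rng_noise.standard_normal((len(genes), len(sample_ids)))
    )

    gene_pos = {g: i for i, g in enumerate(genes)}
    planted_rows = []
    for sig_name, label, delta in config.planted_effects:
        sig = by_name[sig_name]
        cols = np.asarray(annotation.to_numpy() == label)
        for g in sorted(sig.genes):
            shift = sig.direction(g) * delta
            values[gene_pos[g], cols] += shift
            if shift != 0:
                planted_rows.append(
                    {"gene": g, "subtype": label, "shift": float(shift)}
                )

    matrix = pd.DataFrame(values, index=baseline.index,
                          columns=annotation.index)
    membership = pd.DataFrame(
        [
            {"gene": g, "signature": s.name, "direction": int(d)}
            for s in signatures
            for g, d in sorted(s.entries.items())
        ],
        columns=["gene", "signature", "direction"],
    )
    truth = GroundTruth(
        baseline=baseline,
        planted=pd.DataFrame(planted_rows, columns=["gene", "subtype", "shift"]),
        membership=membership,
    )
    return matrix, annotation, truth


def random_signature(
    name: str,
    genes: Sequence[str],
    size: int,
    rng: np.random.Generator,
    frac_up: float = 1.0,
) -> GeneSignature:
    """Random directional signature over a gene universe (test helper)."""
    if size > len(genes):
        raise ValueError("signature larger than gene universe")
    chosen = rng.choice(np.asarray(genes, dtype=object), size=size, replace=False)
    n_up = int(round(frac_up * size))
    directions = [1] * n_up + [-1] * (size - n_up)
    return GeneSignature(
        name=name,
        entries={str(g): d for g, d in zip(chosen, directions)},
        provenance="simulated",
    )


def simulate_qpcr(
    curve_params: Mapping[str, tuple[float, float]],
    sample_truth: Mapping[str, float],
    seed: int = 0,
    target: str = "Met",
    control: str = "Actl6a",
    dilution_log10: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0),
    base_log10_quantity: float = 1.0,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate a qPCR plate: standard dilution series plus samples.

    ``curve_params`` maps assay -> (slope, intercept) of the true line
    ``Ct = intercept + slope * log10(quantity)``; ``sample_truth`` maps
    sample_id -> true relative target copy number (1 = reference level).
    Sample template quantities are proportional to the planted copy number
    for the target assay and constant for the control assay; Gaussian noise
    of sd ``noise_sd`` is added to every Ct.

    Returns a long-format table with columns ``well``, ``sample_id``,
    ``assay``, ``role`` (standard|sample), ``log10_quantity`` (NaN for
    samples) and ``ct``.
    """
    dilution = [float(q) for q in dilution_log10]
    if len(set(dilution)) < 2:
        raise ValueError("dilution series needs >= 2 distinct log10 quantities")
    for assay in (target, control):
        if assay not in curve_params:
            raise ValueError(f"missing curve parameters for assay {assay!r}")
    for assay, (slope, intercept) in curve_params.items():
        if not (np.isfinite(slope) and np.isfinite(intercept)):
            raise ValueError(f"non-finite curve parameters for {assay!r}")
    (rng,) = _sub_rngs(seed, 1)

    rows = []
    well = 0

    def ct_of(assay: str, log10_q: float) -> float:
        slope, intercept = curve_params[assay]
        return intercept + slope * log10_q + noise_sd * rng.standard_normal()

    for assay in sorted(curve_params):
        for log10_q in dilution:
            for _ in range(n_replicates):
                well += 1
                rows.append(
                    {"well": f"W{well:03d}", "sample_id": "", "assay": assay,
                     "role": "standard", "log10_quantity": log10_q,
                     "ct": ct_of(assay, log10_q)}
                )
    for sid in sample_truth:
        copy = float(sample_truth[sid])
        if copy <= 0:
            raise ValueError(f"planted copy number must be > 0 ({sid!r})")
        for assay in sorted(curve_params):
            log10_q = base_log10_quantity
            if assay == target:
                log10_q = base_log10_quantity + np.log10(copy)
            for _ in range(n_replicates):
                well += 1
                rows.append(
                    {"well": f"W{well:03d}", "sample_id": sid, "assay": assay,
                     "role": "sample", "log10_quantity": np.nan,
                     "ct": ct_of(assay, log10_q)}
                )
    return pd.DataFrame(rows)


def _draw_counts(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n non-negative integer counts from a distribution spec.

    Specs: an int (constant), ``("poisson", lam)``, or
    ``("mixture", [(weight, spec), ...])``.
    """
    if isinstance(spec, (int, np.integer)):
        if spec < 0:
            raise ValueError("counts must be non-negative")
        return np.full(n, int(spec), dtype=int)
    kind = spec[0]
    if kind == "poisson":
        return rng.poisson(float(spec[1]), size=n).astype(int)
    if kind == "mixture":
        weights = np.array([w for w, _ in spec[1]], dtype=float)
        weights = weights / weights.sum()
        which = rng.choice(len(weights), size=n, p=weights)
        out = np.empty(n, dtype=int)
        for i, (_, sub) in enumerate(spec[1]):
            mask = which == i
            out[mask] = _draw_counts(sub, int(mask.sum()), rng)
        return out
    raise ValueError(f"unknown distribution spec {spec!r}")


def simulate_fish_cells(
    n_cells: int, target_dist, centromere_dist, seed: int = 0
) -> pd.DataFrame:
    """Simulate a per-cell FISH count table (cell_id, met_count, cen7_count)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng_t, rng_c = _sub_rngs(seed, 2)
    return pd.DataFrame(
        {
            "cell_id": [f"C{i + 1:04d}" for i in range(n_cells)],
            "met_count": _draw_counts(target_dist, n_cells, rng_t),
            "cen7_count": _draw_counts(centromere_dist, n_cells, rng_c),
        }
    )
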
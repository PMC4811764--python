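"""Directional gene signatures and the operations that construct them.

A signature is a named collection of genes, each tagged with a direction
(+1 for genes expected high in the state of interest, -1 for genes expected
low).  Signatures can be built by intersecting two existing signatures, by
differential expression between two sample groups, or restricted to the
genes measured on a given platform.  Cross-species gene sets are translated
through a homolog map before intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSignature",
    "HomologMap",
    "HomologReport",
    "map_homologs",
    "intersect_signatures",
    "derive_de_signature",
    "restrict_to_platform",
    "read_gmt",
    "write_gmt",
]

_UP, _DN = "_UP", "_DN"


@dataclass(frozen=True)
class GeneSignature:
    """A named set of (gene, direction) entries.

    Parameters
    ----------
    name:
        Signature identifier.
    entries:
        Mapping ``gene_id -> direction`` with direction in ``{+1, -1}``.
    provenance:
        Free-text note on how the signature was obtained.
    """

    name: str
    entries: Mapping[str, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.entries.items() if d not in (1, -1)}
        if bad:
            raise ValueError(f"directions must be +1 or -1, got {bad}")
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    @property
    def up_genes(self) -> set[str]:
        return {g for g, d in self.entries.items() if d == 1}

    @property
    def down_genes(self) -> set[str]:
        return {g for g, d in self.entries.items() if d == -1}

    def direction(self, gene: str) -> int:
        return self.entries[gene]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries


class HomologMap:
    """One-to-many mapping from source gene IDs to target gene IDs.

    Lookup of an unmapped source ID yields an empty set rather than an
    error; empty target sets are never stored.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        mapping: dict[str, set[str]] = {}
        for row in pairs:
            try:
                src, tgt = row
            except ValueError as exc:
                raise ValueError(f"malformed homolog pair: {row!r}") from exc
            if not src or not tgt:
                raise ValueError(f"malformed homolog pair: {row!r}")
            mapping.setdefault(str(src), set()).add(str(tgt))
        self._map = mapping

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologMap":
        """Read a two-column (source_id, target_id) TSV, one row per pair."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(fields)}"
                    )
                pairs.append((fields[0], fields[1]))
        return cls(pairs)

    def __getitem__(self, source: str) -> set[str]:
        return set(self._map.get(source, set()))

    def __len__(self) -> int:
        return len(self._map)

    def sources(self) -> set[str]:
        return set(self._map)


@dataclass
class HomologReport:
    """Outcome of a homolog translation."""

    mapped: set[str]
    unmapped: set[str] = field(default_factory=set)
    ambiguous: set[str] = field(default_factory=set)


def map_homologs(
    genes: Iterable[str], homolog_map: HomologMap, policy: str = "expand"
) -> HomologReport:
    """Translate a gene set through a homolog map.

    ``policy="expand"`` unions all targets of every source gene;
    ``policy="unique_only"`` keeps only sources with exactly one target and
    records one-to-many sources as ambiguous.  Sources with no targets are
    recorded as unmapped, never silently lost.
    """
    if policy not in ("expand", "unique_only"):
        raise ValueError(f"unknown policy {policy!r}")
    mapped: set[str] = set()
    unmapped: set[str] = set()
    ambiguous: set[str] = set()
    for g in genes:
        targets = homolog_map[g]
        if not targets:
            unmapped.add(g)
        elif policy == "expand":
            mapped |= targets
        elif len(targets) == 1:
            mapped |= targets
        else:
            ambiguous.add(g)
    return HomologReport(mapped=mapped, unmapped=unmapped, ambiguous=ambiguous)


def intersect_signatures(
    a: GeneSignature, b: GeneSignature, name: str | None = None
) -> tuple[GeneSignature, set[str]]:
    """Overlap two signatures, keeping genes with concordant direction.

    Genes present in both signatures but with opposite directions cannot be
    assigned a sign; they are dropped and returned as the second element.
    The result is symmetric in ``a`` and ``b``.
    """
    shared = a.genes & b.genes
    entries = {g: a.entries[g] for g in shared if a.entries[g] == b.entries[g]}
    discordant = shared - set(entries)
    if discordant:
        warnings.warn(
            f"{len(discordant)} gene(s) with discordant direction dropped "
            f"from {a.name} ∩ {b.name}: {sorted(discordant)}"
        )
    if not entries:
        warnings.warn(f"empty intersection of {a.name} and {b.name}")
    sig = GeneSignature(
        name=name or f"{a.name}_x_{b.name}",
        entries=entries,
        provenance=f"overlap of {a.name} and {b.name}",
    )
    return sig, discordant


def derive_de_signature(
    x: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    alpha: float = 0.05,
    equal_var: bool = True,
    name: str = "DE",
) -> tuple[pd.DataFrame, GeneSignature]:
    """Differential-expression signature between two sample groups.

    Per gene, a two-sample t-test (pooled variance by default, Welch when
    ``equal_var=False``) of group A vs group B, Benjamini–Hochberg adjusted
    across all tested genes.  The signature contains genes with adjusted
    p <= ``alpha``, direction = sign of (mean A - mean B).

    Returns the per-gene result table (columns ``statistic``, ``pvalue``,
    ``p_adjusted``, ``direction``, ``degenerate``) and the signature.

    Notes
    -----
    Genes with zero variance in both groups get p = 1 when the group means
    are equal; when the means differ the t statistic is infinite and the
    gene is flagged ``degenerate`` with p = 0.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")

    va = x[group_a].to_numpy(float)
    vb = x[group_b].to_numpy(float)
    mean_diff = va.mean(axis=1) - vb.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(va, vb, axis=1, equal_var=equal_var)

    zero_var = (va.var(axis=1) == 0) & (vb.var(axis=1) == 0)
    equal_means = np.isclose(mean_diff, 0.0)
    degenerate = zero_var & ~equal_means
    t = np.where(zero_var & equal_means, 0.0, t)
    p = np.where(zero_var & equal_means, 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(mean_diff) * np.inf, t)
    p = np.where(degenerate, 0.0, p)

    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    direction = np.sign(mean_diff).astype(int)

    result = pd.DataFrame(
        {
            "statistic": t,
            "pvalue": p,
            "p_adjusted": p_adj,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=x.index,
    )

    selected = result[(result["p_adjusted"] <= alpha) & (result["direction"] != 0)]
    sig = GeneSignature(
        name=name,
        entries={g: int(d) for g, d in selected["direction"].items()},
        provenance=(
            f"two-sample t ({'pooled' if equal_var else 'Welch'}), "
            f"BH-adjusted p <= {alpha}"
        ),
    )
    return result, sig


def restrict_to_platform(
    sig: GeneSignature, platform_genes: Iterable[str]
) -> tuple[GeneSignature, float]:
    """Filter a signature to genes measured on a platform.

    Returns the restricted signature and the coverage fraction
    (kept genes / signature genes; 1.0 for an empty signature).
    """
    platform = set(platform_genes)
    entries = {g: d for g, d in sig.entries.items() if g in platform}
    coverage = len(entries) / len(sig) if len(sig) else 1.0
    restricted = GeneSignature(
        name=sig.name,
        entries=entries,
        provenance=f"{sig.provenance}; restricted to platform "
        f"(coverage {coverage:.3f})".lstrip("; "),
    )
    return restricted, coverage


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    """Write signatures as GMT, two records each: ``NAME_UP`` and ``NAME_DN``.

    Records with no genes are omitted (GMT does not allow empty sets).
    """
    with open(path, "w") as fh:
        for sig in signatures:
            for suffix, genes in ((_UP, sig.up_genes), (_DN, sig.down_genes)):
                if genes:
                    desc = sig.provenance or "na"
                    fh.write(
                        "\t".join([sig.name + suffix, desc, *sorted(genes)]) + "\n"
                    )


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read GMT records, pairing ``NAME_UP`` / ``NAME_DN`` into signatures.

    A record without the ``_UP``/``_DN`` suffix is treated as all-up.
    """
    raw: dict[str, dict[str, int]] = {}
    prov: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT record needs >= 3 fields")
            rec_name, desc, genes = fields[0], fields[1], fields[2:]
            if rec_name.endswith(_UP):
                name, d = rec_name[: -len(_UP)], 1
            elif rec_name.endswith(_DN):
                name, d = rec_name[: -len(_DN)], -1
            else:
                name, d = rec_name, 1
            if name not in raw:
                raw[name] = {}
                order.append(name)
                prov[name] = desc
            for g in genes:
                if g:
                    raw[name][g] = d
    return [
        GeneSignature(name=n, entries=raw[n], provenance=prov[n]) for n in order
    ]
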
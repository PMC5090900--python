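"""Property-vs-sequence-identity correlation with leave-one-out checks.

A scalar enzyme property (relative activity, a specificity fraction,
solubility or expression) is paired with each variant's percent identity to
a named reference sequence, and the Pearson correlation is computed with
and without a designated point.  The leave-one-out comparison is the
robustness check that distinguishes a genuine identity-property trend from
one carried by a single high-leverage point (typically the reference
itself, which sits at identity 100).

The reference's self-point is excluded by default; no p-values are
attached by default, but a seeded permutation p-value is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .identity import IdentityMatrix


@dataclass
class PropertyVector:
    """Paired (property, identity-to-reference) values over variants."""

    ids: list[str]
    properties: np.ndarray
    identities: np.ndarray
    reference_id: str
    property_name: str = "property"

    def __post_init__(self) -> None:
        self.properties = np.asarray(self.properties, dtype=float)
        self.identities = np.asarray(self.identities, dtype=float)
        n = len(self.ids)
        if self.properties.shape != (n,) or self.identities.shape != (n,):
            raise ValueError("ids, properties and identities must have equal length")
        if np.isnan(self.properties).any() or np.isnan(self.identities).any():
            raise ValueError("paired entries must be complete (no NaN)")
        if self.identities.min() < 0 or self.identities.max() > 100:
            raise ValueError("identities must lie in [0, 100]")

    def without(self, drop_id: str) -> "PropertyVector":
        if drop_id not in self.ids:
            raise KeyError(f"id {drop_id!r} not in property vector")
        keep = [i for i, rid in enumerate(self.ids) if rid != drop_id]
        return PropertyVector(
            ids=[self.ids[i] for i in keep],
            properties=self.properties[keep],
            identities=self.identities[keep],
            reference_id=self.reference_id,
            property_name=self.property_name,
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"id\t{self.property_name}\tidentity_to_{self.reference_id}\n")
            for rid, prop, ident in zip(self.ids, self.properties, self.identities):
                fh.write(f"{rid}\t{prop:.6g}\t{ident:.6g}\n")


def build_property_vector(
    values: dict[str, float],
    identity: IdentityMatrix,
    reference_id: str,
    property_name: str = "property",
    include_reference: bool = False,
) -> PropertyVector:
    """Pair per-variant property values with identity to *reference_id*.

    Variants whose property is NaN (e.g. not-determined activities) are
    dropped; the reference's own identity-100 point is excluded unless
    ``include_reference`` — its in/exclusion is exactly what the
    leave-one-out check probes.
    """
    if reference_id not in identity.ids:
        raise KeyError(f"reference {reference_id!r} not in identity matrix")
    ids, props, idents = [], [], []
    for rid, value in values.items():
        if rid == reference_id and not include_reference:
            continue
        if rid not in identity.ids or np.isnan(value):
            continue
        ids.append(rid)
        props.append(float(value))
        idents.append(identity.get(rid, reference_id))
    return PropertyVector(
        ids=ids,
        properties=np.array(props),
        identities=np.array(idents),
        reference_id=reference_id,
        property_name=property_name,
    )


def pearson(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 points, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def leave_one_out(pv: PropertyVector, drop_id: str) -> tuple[float, float]:
    """Pearson r with all points and with *drop_id* removed."""
    r_full = pearson(pv.identities, pv.properties)
    reduced = pv.without(drop_id)
    if len(reduced.ids) < 3:
        raise ValueError("dropping the point leaves fewer than 3 observations")
    r_dropped = pearson(reduced.identities, reduced.properties)
    return r_full, r_dropped


def permutation_pvalue(x, y, n_permutations: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for |r| under label shuffling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    observed = abs(pearson(x, y))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if abs(pearson(x, rng.permutation(y))) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def correlation_report(
    pv: PropertyVector, drop_id: str | None = None
) -> dict[str, float | str | int]:
    """Summary mapping for TSV/JSON output."""
    out: dict[str, float | str | int] = {
        "property": pv.property_name,
        "reference_id": pv.reference_id,
        "n": len(pv.ids),
        "r": pearson(pv.identities, pv.properties),
    }
    if drop_id is not None and drop_id in pv.ids:
        _, r_dropped = leave_one_out(pv, drop_id)
        out["dropped_id"] = drop_id
        out["r_without_dropped"] = r_dropped
    return out
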
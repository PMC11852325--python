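"""Pairwise spatial-overlap indices between species density distributions.

Four complementary niche-overlap indices (Levins, Schoener, Pianka,
Morisita-Horn) computed on area-weighted proportion vectors

    p(i) = a(i) d(i) / sum_i a(i) d(i),

which is the normalization under which Schoener, Pianka and Morisita-Horn
respect their stated [0, 1] range.  Levins' index is asymmetric and can
exceed 1 even on proportions; values above 1 are reported as computed and
flagged with a warning rather than clipped.  A raw-density mode (no
normalization) is available behind the ``proportions`` flag.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def to_proportions(d, area=None) -> np.ndarray:
    """Area-weighted proportion vector of one species' density field."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be non-negative")
    w = d if area is None else d * np.asarray(area, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("density is zero everywhere: proportions undefined")
    return w / total


def _check_pair(p1, p2):
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("proportion vectors must have equal length")
    return p1, p2


def levins(p1, p2) -> float:
    """Levins' overlap of species 2 on species 1's distribution:
    sum(p1*p2) / sum(p1^2).  Asymmetric; the first argument is the species
    whose distribution forms the denominator."""
    p1, p2 = _check_pair(p1, p2)
    denom = (p1 ** 2).sum()
    if denom == 0:
        raise ValueError("first proportion vector is all zero")
    value = float((p1 * p2).sum() / denom)
    if value > 1:
        logger.warning("Levins overlap %.4f exceeds 1 (index is unbounded "
                       "above for uneven distributions)", value)
    return value


def schoener(p1, p2) -> float:
    """Schoener's overlap: 1 - 0.5 * sum |p1 - p2|, in [0, 1]."""
    p1, p2 = _check_pair(p1, p2)
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def pianka(p1, p2) -> float:
    """Pianka's overlap: cosine similarity of the proportion vectors."""
    p1, p2 = _check_pair(p1, p2)
    denom = np.sqrt((p1 ** 2).sum() * (p2 ** 2).sum())
    if denom == 0:
        raise ValueError("zero proportion vector")
    return float((p1 * p2).sum() / denom)


def morisita_horn(p1, p2) -> float:
    """Morisita-Horn overlap: 2*sum(p1*p2) / (sum p1^2 + sum p2^2)."""
    p1, p2 = _check_pair(p1, p2)
    denom = (p1 ** 2).sum() + (p2 ** 2).sum()
    if denom == 0:
        raise ValueError("zero proportion vectors")
    return float(2.0 * (p1 * p2).sum() / denom)


INDICES = {"levins": levins, "schoener": schoener, "pianka": pianka,
           "morisita_horn": morisita_horn}


def overlap_table(fields, proportions: bool = True) -> pd.DataFrame:
    """All four indices for all species pairs, per time and scenario.

    ``fields`` is a DensityField or an iterable of them (one per scenario).
    Levins is reported in listed pair order (pair "A-B" means B's overlap on
    A's distribution).  Pairs involving a species with zero total density
    are omitted with a warning.
    """
    try:
        iter(fields)
    except TypeError:
        fields = [fields]
    rows = []
    for field in fields:
        C = len(field.species)
        if C < 2:
            raise ValueError("need at least two species for overlap indices")
        area = field.mesh.cell_area_km2
        for ti, tm in enumerate(field.times):
            props = {}
            for ci, sp in enumerate(field.species):
                d = field.d[:, ci, ti]
                if d.sum() <= 0:
                    logger.warning("species %s has zero density at time %s "
                                   "(%s); pair rows omitted", sp, tm,
                                   field.scenario)
                    continue
                props[ci] = (to_proportions(d, area) if proportions
                             else d.astype(float))
            for i, j in itertools.combinations(range(C), 2):
                if i not in props or j not in props:
                    continue
                pair = f"{field.species[i]}-{field.species[j]}"
                for name, fn in INDICES.items():
                    rows.append({"pair": pair, "index": name,
                                 "scenario": field.scenario, "time": tm,
                                 "value": fn(props[i], props[j])})
    return pd.DataFrame(rows)
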
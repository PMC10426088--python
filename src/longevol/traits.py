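"""Longevity quotients and the long-lived / control partition.

The longevity quotient LQ is the ratio of a species' observed maximum
lifespan (MLS, years) to the lifespan its adult body mass (BM, grams)
predicts under the mammalian allometry

    LQ = MLS / (6.32 * BM**0.139)

so LQ > 1 means living longer than size alone predicts.  A cohort is
partitioned by the mean-plus-one-standard-deviation rule: species with LQ
strictly above mean(LQ) + sd(LQ) are long-lived, everything else is
control.  The sample (n-1) standard deviation is used; ties at the
threshold go to the control group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ALLOMETRIC_COEF = 6.32
ALLOMETRIC_EXP = 0.139


class TraitError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesTraits:
    species_id: str
    mls: float  # maximum lifespan, years
    bm: float   # adult body mass, grams
    lq: float
    long_lived: bool | None = None


@dataclass(frozen=True)
class LongevityPartition:
    threshold: float
    long_lived: frozenset[str]
    control: frozenset[str]
    lq: dict[str, float]

    @property
    def cohort(self) -> frozenset[str]:
        return self.long_lived | self.control


def compute_lq(mls: float, bm: float) -> float:
    """Longevity quotient for one species; mls in years, bm in grams."""
    values = {}
    for name, value in (("mls", mls), ("bm", bm)):
        try:
            value = float(value)
        except (TypeError, ValueError):
            raise TraitError(f"{name} must be a number, got {value!r}") from None
        if not math.isfinite(value):
            raise TraitError(f"{name} must be finite, got {value!r}")
        if value <= 0:
            raise TraitError(f"{name} must be > 0, got {value}")
        values[name] = value
    return values["mls"] / (ALLOMETRIC_COEF * values["bm"] ** ALLOMETRIC_EXP)


def partition_cohort(
    traits, *, ddof: int = 1, strict: bool = True
) -> LongevityPartition:
    """Split a cohort at mean(LQ) + 1 sd(LQ).

    ``traits`` is an iterable of (species_id, mls, bm) tuples or
    :class:`SpeciesTraits`.  ``ddof=1`` (sample sd) is the default;
    ``strict`` keeps the > comparison so threshold ties fall to control.
    """
    rows = []
    for t in traits:
        if isinstance(t, SpeciesTraits):
            rows.append((t.species_id, t.mls, t.bm))
        else:
            rows.append(tuple(t)[:3])
    if len(rows) < 2:
        raise TraitError(f"cohort too small: need >= 2 species, got {len(rows)}")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise TraitError(f"duplicate species_id: {dup}")
    lq = {sid: compute_lq(mls, bm) for sid, mls, bm in rows}
    values = np.array(list(lq.values()))
    threshold = float(values.mean() + values.std(ddof=ddof))
    if strict:
        flagged = {s for s, v in lq.items() if v > threshold}
    else:
        flagged = {s for s, v in lq.items() if v >= threshold}
    return LongevityPartition(
        threshold=threshold,
        long_lived=frozenset(flagged),
        control=frozenset(lq) - frozenset(flagged),
        lq=lq,
    )


def log10_traits(values, label: str = "trait"):
    """Element-wise log10 with an error naming the offending entry.

    Accepts a mapping (returns a mapping) or a sequence (returns ndarray).
    """
    if isinstance(values, dict):
        out = {}
        for k, v in values.items():
            if not (math.isfinite(v) and v > 0):
                raise TraitError(f"{label} for {k!r} must be > 0 to log-transform, got {v}")
            out[k] = math.log10(v)
        return out
    arr = np.asarray(values, dtype=float)
    bad = ~(np.isfinite(arr) & (arr > 0))
    if bad.any():
        idx = int(np.argwhere(bad)[0])
        raise TraitError(
            f"{label}[{idx}] must be > 0 to log-transform, got {arr.flat[idx]}"
        )
    return np.log10(arr)


# -- tabular IO ---------------------------------------------------------------

TRAIT_COLUMNS = ["species", "mls_years", "bm_g"]


def read_trait_table(path) -> pd.DataFrame:
    """TSV/CSV with header columns species, mls_years, bm_g."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise TraitError(f"trait table missing column(s) {missing}")
    return df[TRAIT_COLUMNS]


def partition_from_table(df: pd.DataFrame, **kwargs) -> LongevityPartition:
    return partition_cohort(
        df[TRAIT_COLUMNS].itertuples(index=False, name=None), **kwargs
    )


def write_partition(partition: LongevityPartition, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# lq_threshold\t{partition.threshold:.6f}\n")
        fh.write("species\tlq\tlong_lived\n")
        for sp in sorted(partition.lq):
            flag = int(sp in partition.long_lived)
            fh.write(f"{sp}\t{partition.lq[sp]:.6f}\t{flag}\n")
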
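"""Assembly of taxonomically matched invasive/non-invasive species pairs.

Each non-invasive species is matched to invasive relatives from the same
continent of origin at the tightest available taxonomic rank — genus, then
tribe, then subfamily, then family.  When several invasive species tie at
the tightest rank, all are kept and their trait values averaged, which is
more conservative than picking one subjectively.  A non-invasive species is
used in at most one pair; an invasive species may serve in several pairs.
Biocontrol or otherwise intentionally introduced species, stored-product
pests and cryptogenic species are excluded before matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import PairingError, ValidationError

logger = logging.getLogger(__name__)

CONTINENTS = frozenset(
    {"Europe", "North_America", "Asia", "Africa", "Oceania", "South_America"}
)
EXCLUSION_FLAGS = frozenset(
    {"biocontrol_or_intentional", "stored_product", "cryptogenic"}
)
#: Matching ranks, tightest first.
RANKS = ("genus", "tribe", "subfamily", "family")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species with taxonomy, origin, invasive status and trait values."""

    species_id: str
    order: str
    family: str
    genus: str
    continent: str
    invasive: bool
    subfamily: str | None = None
    tribe: str | None = None
    flags: frozenset[str] = field(default_factory=frozenset)
    ldt: float | None = None  # °C
    set_dd: float | None = None  # D°

    def __post_init__(self) -> None:
        for name in ("order", "family", "genus"):
            if not getattr(self, name):
                raise ValidationError(f"{self.species_id}: empty {name}")
        if self.continent not in CONTINENTS:
            raise ValidationError(
                f"{self.species_id}: unknown continent {self.continent!r}"
            )
        unknown = set(self.flags) - EXCLUSION_FLAGS
        if unknown:
            raise ValidationError(f"{self.species_id}: unknown flags {sorted(unknown)}")

    def rank_key(self, rank: str) -> tuple | None:
        """Hashable identity of this species at ``rank``; None if the rank is absent."""
        if rank == "genus":
            return (self.order, self.family, self.genus)
        if rank == "tribe":
            return (self.order, self.family, self.tribe) if self.tribe else None
        if rank == "subfamily":
            return (self.order, self.family, self.subfamily) if self.subfamily else None
        if rank == "family":
            return (self.order, self.family)
        raise ValueError(f"unknown rank {rank!r}")


@dataclass(frozen=True)
class SpeciesPair:
    """One comparison unit: a non-invasive species vs an invasive group."""

    pair_id: str
    noninvasive: str
    invasive_members: tuple[str, ...]
    relatedness_rank: str
    continent: str
    ldt_noninv: float
    ldt_inv: float
    set_noninv: float | None = None
    set_inv: float | None = None

    @property
    def d_ldt(self) -> float:
        """LDT difference, invasive minus non-invasive (°C)."""
        return self.ldt_inv - self.ldt_noninv

    @property
    def d_set(self) -> float | None:
        """SET difference, invasive minus non-invasive (D°); None if missing."""
        if self.set_noninv is None or self.set_inv is None:
            return None
        return self.set_inv - self.set_noninv


def _mean_or_none(values: list[float | None]) -> float | None:
    present = [v for v in values if v is not None]
    return float(np.mean(present)) if present else None


def match_pairs(records: Sequence[SpeciesRecord]) -> list[SpeciesPair]:
    """Build all pairs from a deduplicated species table.

    Flagged records are removed first (and logged).  For every eligible
    non-invasive species the invasive candidates from the same continent are
    searched rank by rank, genus outward to family; all candidates tied at
    the tightest matching rank are averaged into a single invasive value.
    Non-invasive species without any same-continent relative at family rank
    or tighter are dropped and logged.
    """
    seen: set[str] = set()
    for rec in records:
        if rec.species_id in seen:
            raise PairingError(f"duplicate species_id {rec.species_id!r}")
        seen.add(rec.species_id)

    eligible = []
    for rec in records:
        if rec.flags:
            logger.info("excluded %s (flags: %s)", rec.species_id, sorted(rec.flags))
        else:
            eligible.append(rec)

    invasive = [r for r in eligible if r.invasive]
    noninvasive = sorted(
        (r for r in eligible if not r.invasive), key=lambda r: r.species_id
    )

    pairs: list[SpeciesPair] = []
    reuse_count: dict[str, int] = {}
    for ni in noninvasive:
        if ni.ldt is None:
            logger.info("unpaired %s: no LDT value", ni.species_id)
            continue
        matched = None
        for rank in RANKS:
            key = ni.rank_key(rank)
            if key is None:
                continue
            candidates = [
                inv
                for inv in invasive
                if inv.continent == ni.continent
                and inv.ldt is not None
                and inv.rank_key(rank) == key
            ]
            if candidates:
                matched = (rank, sorted(candidates, key=lambda r: r.species_id))
                break
        if matched is None:
            logger.info(
                "unpaired %s: no same-continent invasive relative at family rank "
                "or tighter", ni.species_id,
            )
            continue
        rank, members = matched
        for m in members:
            reuse_count[m.species_id] = reuse_count.get(m.species_id, 0) + 1
        pairs.append(
            SpeciesPair(
                pair_id=f"P{len(pairs) + 1:03d}",
                noninvasive=ni.species_id,
                invasive_members=tuple(m.species_id for m in members),
                relatedness_rank=rank,
                continent=ni.continent,
                ldt_noninv=float(ni.ldt),
                ldt_inv=float(np.mean([m.ldt for m in members])),
                set_noninv=ni.set_dd,
                set_inv=_mean_or_none([m.set_dd for m in members]),
            )
        )
    reused = {k: v for k, v in reuse_count.items() if v > 1}
    if reused:
        logger.info("invasive species reused across pairs: %s", reused)
    return pairs


def pair_differences(pairs: Sequence[SpeciesPair]) -> pd.DataFrame:
    """Per-pair trait differences (invasive minus non-invasive).

    ``d_set`` is NaN where either member lacks a SET value, which is what
    produces unequal LDT/SET sample sizes downstream.
    """
    if not pairs:
        raise ValidationError("no pairs supplied")
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "d_ldt": [p.d_ldt for p in pairs],
            "d_set": [np.nan if p.d_set is None else p.d_set for p in pairs],
        }
    )


def pairs_to_frame(pairs: Sequence[SpeciesPair]) -> pd.DataFrame:
    """Serialize pairs to the delimited output schema."""
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "noninvasive_id": [p.noninvasive for p in pairs],
            "invasive_ids": [";".join(p.invasive_members) for p in pairs],
            "relatedness_rank": [p.relatedness_rank for p in pairs],
            "continent": [p.continent for p in pairs],
            "ldt_noninv": [p.ldt_noninv for p in pairs],
            "ldt_inv": [p.ldt_inv for p in pairs],
            "set_noninv": [p.set_noninv for p in pairs],
            "set_inv": [p.set_inv for p in pairs],
            "d_ldt": [p.d_ldt for p in pairs],
            "d_set": [p.d_set for p in pairs],
        }
    )


def pairs_to_long(pairs: Sequence[SpeciesPair], trait: str = "ldt") -> pd.DataFrame:
    """Two rows per pair (status 0 = non-invasive, 1 = invasive) for mixed models.

    Pairs lacking the requested trait on either side are omitted.
    """
    if trait not in ("ldt", "set"):
        raise ValidationError(f"trait must be 'ldt' or 'set', got {trait!r}")
    rows = []
    for p in pairs:
        if trait == "ldt":
            lo, hi = p.ldt_noninv, p.ldt_inv
        else:
            if p.set_noninv is None or p.set_inv is None:
                continue
            lo, hi = p.set_noninv, p.set_inv
        rows.append({"pair_id": p.pair_id, "status": 0, "value": lo})
        rows.append({"pair_id": p.pair_id, "status": 1, "value": hi})
    return pd.DataFrame(rows)


def long_from_pairs_frame(pairs_frame: pd.DataFrame, trait: str = "ldt") -> pd.DataFrame:
    """Long format (two rows per pair) from a pair table DataFrame.

    Accepts the serialized pair schema (``ldt_noninv``/``ldt_inv`` or
    ``set_noninv``/``set_inv`` columns); pairs with a missing value on
    either side are omitted.
    """
    if trait not in ("ldt", "set"):
        raise ValidationError(f"trait must be 'ldt' or 'set', got {trait!r}")
    lo_col, hi_col = f"{trait}_noninv", f"{trait}_inv"
    frame = pairs_frame.dropna(subset=[lo_col, hi_col])
    n = len(frame)
    return pd.DataFrame(
        {
            "pair_id": np.repeat(frame["pair_id"].to_numpy(), 2),
            "status": np.tile([0, 1], n),
            "value": np.column_stack(
                [frame[lo_col].to_numpy(), frame[hi_col].to_numpy()]
            ).ravel(),
        }
    )


def records_from_frame(frame: pd.DataFrame) -> list[SpeciesRecord]:
    """Build validated records from a species trait table."""
    required = {"species_id", "order", "family", "genus", "continent", "invasive"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"species table missing columns: {sorted(missing)}")

    def _opt(row, col):
        if col not in frame.columns:
            return None
        v = row[col]
        return None if pd.isna(v) or v == "" else v

    records = []
    for _, row in frame.iterrows():
        flags_raw = _opt(row, "flags")
        flags = frozenset(f for f in str(flags_raw).split(";") if f) if flags_raw else frozenset()
        ldt = _opt(row, "ldt_c")
        set_dd = _opt(row, "set_dd")
        records.append(
            SpeciesRecord(
                species_id=str(row["species_id"]),
                order=str(row["order"]),
                family=str(row["family"]),
                genus=str(row["genus"]),
                subfamily=_opt(row, "subfamily"),
                tribe=_opt(row, "tribe"),
                continent=str(row["continent"]),
                invasive=bool(int(row["invasive"])),
                flags=flags,
                ldt=None if ldt is None else float(ldt),
                set_dd=None if set_dd is None else float(set_dd),
            )
        )
    return records
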
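"""Data model and I/O for multilocus microsatellite genotype tables.

A reference database (GRDB) holds diploid genotypes of individuals sampled
at known localities.  Alleles are arbitrary non-negative integer labels
(typically fragment sizes in base pairs); half-called loci are demoted to
missing, so a call is always an unordered pair of alleles or absent.

Two CSV dialects are supported:

* **wide** — one row per individual, two columns per locus
  (``<locus>_1``, ``<locus>_2``).
* **long** — one row per individual x locus
  (``individual_id, origin, locus, allele1, allele2``).

STRUCTURE-format export (two rows per individual, ``-9`` for missing) is
provided for interoperability with external clustering software.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MISSING_SENTINELS",
    "MultilocusGenotype",
    "Locality",
    "ReferenceDatabase",
    "AlleleCountTable",
    "read_genotype_table",
    "write_genotype_table",
    "write_structure_format",
    "allele_counts",
    "find_duplicates",
    "find_first_order_relatives",
]

#: cell values interpreted as a missing allele on input
MISSING_SENTINELS = ("0", "", "NA", "-9")


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype tables (odd columns, bad sentinels...)."""


def _normalize_call(a, b):
    """Return an order-insensitive allele pair, or None if either is missing."""
    if a is None or b is None:
        return None
    return (a, b) if a <= b else (b, a)


@dataclass
class MultilocusGenotype:
    """One individual: two allele calls per locus, possibly missing.

    ``calls`` maps locus name -> sorted ``(a, b)`` tuple or ``None``.
    ``origin_label`` is the locality of sampling for reference individuals
    and ``None`` for queries of unknown origin.
    """

    individual_id: str
    calls: dict
    origin_label: str | None = None

    def __post_init__(self):
        self.calls = {
            locus: _normalize_call(*pair) if pair is not None else None
            for locus, pair in self.calls.items()
        }
        if all(v is None for v in self.calls.values()):
            raise ValueError(
                f"individual {self.individual_id!r} has no typed locus"
            )

    def typed_loci(self):
        return [loc for loc, v in self.calls.items() if v is not None]

    def is_heterozygous(self, locus):
        pair = self.calls.get(locus)
        return pair is not None and pair[0] != pair[1]


@dataclass
class Locality:
    """A sampling site: name, coordinates, and (optional) genetic cluster."""

    name: str
    latitude: float = float("nan")
    longitude: float = float("nan")
    cluster_id: str | int | None = None


@dataclass
class ReferenceDatabase:
    """Genotype reference database: loci, localities, labeled individuals."""

    loci: list
    localities: list
    individuals: list

    def __post_init__(self):
        names = [loc.name for loc in self.localities]
        if len(set(names)) != len(names):
            raise ValueError("locality names must be unique")
        known = set(names)
        for ind in self.individuals:
            if ind.origin_label is None:
                raise ValueError(
                    f"reference individual {ind.individual_id!r} lacks an origin"
                )
            if ind.origin_label not in known:
                raise ValueError(
                    f"individual {ind.individual_id!r} has unknown origin "
                    f"{ind.origin_label!r}"
                )
            extra = set(ind.calls) - set(self.loci)
            if extra:
                raise ValueError(
                    f"individual {ind.individual_id!r} typed at loci outside "
                    f"the database locus list: {sorted(extra)}"
                )

    @property
    def locality_names(self):
        return [loc.name for loc in self.localities]

    def individuals_of(self, locality_name):
        return [i for i in self.individuals if i.origin_label == locality_name]

    def cluster_map(self):
        """locality name -> cluster id; raises if any cluster id is unset."""
        missing = [l.name for l in self.localities if l.cluster_id is None]
        if missing:
            raise ValueError(f"localities without cluster id: {missing}")
        return {l.name: l.cluster_id for l in self.localities}

    def with_clusters(self, mapping: Mapping):
        """Return a copy whose localities carry cluster ids from ``mapping``."""
        locs = [
            Locality(l.name, l.latitude, l.longitude, mapping[l.name])
            for l in self.localities
        ]
        return ReferenceDatabase(list(self.loci), locs, list(self.individuals))


@dataclass
class AlleleCountTable:
    """Gene-copy counts per allele per locus for one population/unit.

    ``counts[locus]`` maps allele label -> number of gene copies;
    ``genes_sampled[locus]`` is twice the number of individuals typed there.
    """

    population_id: str
    counts: dict
    genes_sampled: dict = field(default=None)

    def __post_init__(self):
        derived = {loc: sum(c.values()) for loc, c in self.counts.items()}
        if self.genes_sampled is None:
            self.genes_sampled = derived
        elif self.genes_sampled != derived:
            raise ValueError(
                f"{self.population_id}: genes_sampled inconsistent with counts"
            )
        if any(v < 0 for c in self.counts.values() for v in c.values()):
            raise ValueError("negative allele count")

    def n_typed(self, locus):
        return self.genes_sampled.get(locus, 0) // 2

    def frequencies(self, locus):
        genes = self.genes_sampled.get(locus, 0)
        if genes == 0:
            return {}
        return {a: c / genes for a, c in self.counts[locus].items() if c > 0}


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_allele(raw, sentinels, where):
    text = str(raw).strip()
    if text.endswith(".0"):
        text = text[:-2]
    if text in sentinels or text.lower() == "nan":
        return None
    try:
        value = int(text)
    except ValueError as exc:
        raise GenotypeFormatError(f"unparseable allele {raw!r} at {where}") from exc
    if value < 0:
        return None
    return value


def _build_database(loci, genotypes, locality_meta=None):
    meta = locality_meta or {}
    seen = []
    for g in genotypes:
        if g.origin_label not in seen:
            seen.append(g.origin_label)
    localities = [
        meta.get(name, Locality(name)) for name in seen
    ]
    return ReferenceDatabase(loci, localities, genotypes)


def read_genotype_table(path, dialect="wide", missing=MISSING_SENTINELS,
                        localities_csv=None):
    """Read a genotype CSV and return a database or a plain genotype list.

    Parameters
    ----------
    path : str or Path
        CSV file.  Wide dialect: columns ``individual_id[, origin]`` then two
        allele columns per locus named ``<locus>_1`` / ``<locus>_2``.  Long
        dialect: ``individual_id[, origin], locus, allele1, allele2``.
    dialect : {"wide", "long"}
    missing : sequence of str
        Cell values treated as missing allele calls.
    localities_csv : optional path
        Locality metadata (columns ``name, latitude, longitude, cluster`` or
        the bundled ``locality_number,...,cluster`` layout); merged into the
        returned database when the table carries origins.

    Returns
    -------
    ReferenceDatabase if an ``origin`` column is present, else a list of
    MultilocusGenotype (queries of unknown origin).
    """
    path = Path(path)
    sentinels = tuple(str(s) for s in missing)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "wide":
        loci, genotypes = _read_wide(df, sentinels, path)
    elif dialect == "long":
        loci, genotypes = _read_long(df, sentinels, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if genotypes and genotypes[0].origin_label is not None:
        meta = _read_locality_meta(localities_csv) if localities_csv else None
        return _build_database(loci, genotypes, meta)
    return genotypes


def _read_wide(df, sentinels, path):
    cols = list(df.columns)
    if not cols or cols[0] != "individual_id":
        raise GenotypeFormatError(f"{path}: first column must be individual_id")
    has_origin = len(cols) > 1 and cols[1] == "origin"
    allele_cols = cols[2:] if has_origin else cols[1:]
    if len(allele_cols) % 2:
        raise GenotypeFormatError(
            f"{path}: odd number of allele columns ({len(allele_cols)})"
        )
    loci = []
    for c1, c2 in zip(allele_cols[::2], allele_cols[1::2]):
        base1 = c1.rsplit("_", 1)[0]
        base2 = c2.rsplit("_", 1)[0]
        if base1 != base2:
            raise GenotypeFormatError(
                f"{path}: allele column pair {c1!r}/{c2!r} disagree on locus"
            )
        loci.append(base1)
    genotypes = []
    for ridx, row in df.iterrows():
        calls = {}
        for locus, c1, c2 in zip(loci, allele_cols[::2], allele_cols[1::2]):
            a = _parse_allele(row[c1], sentinels, f"row {ridx}, column {c1}")
            b = _parse_allele(row[c2], sentinels, f"row {ridx}, column {c2}")
            calls[locus] = _normalize_call(a, b)
        origin = row["origin"] if has_origin and row["origin"] != "" else None
        genotypes.append(MultilocusGenotype(row["individual_id"], calls, origin))
    return loci, genotypes


def _read_long(df, sentinels, path):
    required = {"individual_id", "locus", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise GenotypeFormatError(
            f"{path}: long dialect needs columns {sorted(required)}"
        )
    has_origin = "origin" in df.columns
    loci = list(dict.fromkeys(df["locus"]))
    by_ind: dict = {}
    origins: dict = {}
    for ridx, row in df.iterrows():
        a = _parse_allele(row["allele1"], sentinels, f"row {ridx}, allele1")
        b = _parse_allele(row["allele2"], sentinels, f"row {ridx}, allele2")
        by_ind.setdefault(row["individual_id"], {})[row["locus"]] = \
            _normalize_call(a, b)
        if has_origin:
            origins[row["individual_id"]] = row["origin"] or None
    genotypes = [
        MultilocusGenotype(
            ind, {loc: calls.get(loc) for loc in loci}, origins.get(ind)
        )
        for ind, calls in by_ind.items()
    ]
    return loci, genotypes


def _read_locality_meta(path):
    df = pd.read_csv(path)
    name_col = "locality_number" if "locality_number" in df.columns else "name"
    meta = {}
    for _, row in df.iterrows():
        name = str(row[name_col])
        meta[name] = Locality(
            name,
            float(row.get("latitude", float("nan"))),
            float(row.get("longitude", float("nan"))),
            row.get("cluster"),
        )
    return meta


def write_genotype_table(obj, path, dialect="wide", missing="0"):
    """Write a database or genotype list to CSV in the chosen dialect."""
    if isinstance(obj, ReferenceDatabase):
        loci, genotypes, with_origin = obj.loci, obj.individuals, True
    else:
        genotypes = list(obj)
        loci = list(dict.fromkeys(
            l for g in genotypes for l in g.calls
        ))
        with_origin = any(g.origin_label is not None for g in genotypes)
    rows = []
    if dialect == "wide":
        for g in genotypes:
            row = {"individual_id": g.individual_id}
            if with_origin:
                row["origin"] = g.origin_label or ""
            for locus in loci:
                pair = g.calls.get(locus)
                a, b = (missing, missing) if pair is None else pair
                row[f"{locus}_1"], row[f"{locus}_2"] = a, b
            rows.append(row)
    elif dialect == "long":
        for g in genotypes:
            for locus in loci:
                pair = g.calls.get(locus)
                a, b = (missing, missing) if pair is None else pair
                row = {"individual_id": g.individual_id}
                if with_origin:
                    row["origin"] = g.origin_label or ""
                row.update(locus=locus, allele1=a, allele2=b)
                rows.append(row)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, index=False)


def write_structure_format(db, path):
    """Write STRUCTURE's two-rows-per-individual integer matrix.

    First column individual id, second column the 1-based numeric index of the
    individual's locality; missing calls encoded as ``-9`` in both rows.
    """
    index = {name: i + 1 for i, name in enumerate(db.locality_names)}
    lines = [" ".join(db.loci)]
    for g in db.individuals:
        for which in (0, 1):
            fields = [str(g.individual_id).replace(" ", "_"),
                      str(index[g.origin_label])]
            for locus in db.loci:
                pair = g.calls.get(locus)
                fields.append("-9" if pair is None else str(pair[which]))
            lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Allele counts and individual-level filters
# ---------------------------------------------------------------------------

def allele_counts(db, grouping="locality"):
    """Tabulate gene-copy counts per allele, per locus, per group.

    ``grouping="locality"`` yields one table per locality;
    ``grouping="cluster"`` pools the member localities of each cluster
    (requires every locality to carry a cluster id).
    """
    if grouping == "locality":
        groups = {name: [name] for name in db.locality_names}
    elif grouping == "cluster":
        cmap = db.cluster_map()
        groups = {}
        for name in db.locality_names:
            groups.setdefault(str(cmap[name]), []).append(name)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    tables = []
    for group_id, members in groups.items():
        member_set = set(members)
        counts = {locus: {} for locus in db.loci}
        for g in db.individuals:
            if g.origin_label not in member_set:
                continue
            for locus, pair in g.calls.items():
                if pair is None:
                    continue
                for allele in pair:
                    counts[locus][allele] = counts[locus].get(allele, 0) + 1
        tables.append(AlleleCountTable(group_id, counts))
    return tables


def _shared_loci(g1, g2):
    return [
        loc for loc in g1.calls
        if g1.calls.get(loc) is not None and g2.calls.get(loc) is not None
    ]


def find_duplicates(genotypes, min_shared_loci=None):
    """Pairs of individuals with identical genotypes at all shared loci.

    A pair is flagged when every mutually typed locus carries the identical
    unordered allele pair and the number of shared loci is at least
    ``min_shared_loci`` (default: the full locus list of the first genotype,
    i.e. complete-profile identity).
    """
    genotypes = list(genotypes)
    if len(genotypes) < 2:
        return []
    if min_shared_loci is None:
        min_shared_loci = len(genotypes[0].calls)
    pairs = []
    for g1, g2 in itertools.combinations(genotypes, 2):
        shared = _shared_loci(g1, g2)
        if len(shared) < min_shared_loci:
            continue
        if all(g1.calls[loc] == g2.calls[loc] for loc in shared):
            pairs.append((g1.individual_id, g2.individual_id))
    return pairs


def find_first_order_relatives(genotypes, min_shared_loci=1):
    """Pairs sharing >=1 allele at every mutually typed locus (non-duplicates).

    Parent-offspring pairs always satisfy this (one allele per locus is
    transmitted); unrelated pairs rarely do at 10 diverse loci.  Duplicate
    pairs are excluded — use :func:`find_duplicates` for those.
    """
    genotypes = list(genotypes)
    dupes = set(map(frozenset, find_duplicates(genotypes, min_shared_loci=1)))
    pairs = []
    for g1, g2 in itertools.combinations(genotypes, 2):
        shared = _shared_loci(g1, g2)
        if len(shared) < min_shared_loci:
            continue
        if frozenset((g1.individual_id, g2.individual_id)) in dupes:
            continue
        if all(
            set(g1.calls[loc]) & set(g2.calls[loc]) for loc in shared
        ):
            pairs.append((g1.individual_id, g2.individual_id))
    return pairs
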
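"""Bundled data from the published howler-monkey (Alouatta caraya) study.

Two small tables ship with the package:

* locality metadata for the 15 Argentinian sampling sites of the
  published genotype reference database, including the three genetic
  clusters (P-RP, F-Ch-C, M-RU) those localities group into;
* the published per-individual assignment scores of 22 confiscated
  individuals and 3 corpses of unknown origin, scored against the
  15 localities and the 3 clusters (best match plus score in %, and the
  study's own below-threshold flags).

The full genotype reference database itself is an external deposit
(DOI 10.5281/zenodo.3660723) and is not redistributed here;
:func:`load_reference_database` reads a local copy once downloaded.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "load_localities",
    "load_published_assignment_scores",
    "load_reference_database",
    "threshold_counts",
]


def _data_path(name):
    return resources.files("strassign.data").joinpath(name)


def load_localities():
    """Locality metadata: number, name, coordinates, N, cluster."""
    with resources.as_file(_data_path("acaraya_localities.csv")) as p:
        return pd.read_csv(p)


def load_published_assignment_scores():
    """Published best-match scores for the 25 individuals of unknown origin."""
    with resources.as_file(_data_path("acaraya_assignment_scores.csv")) as p:
        return pd.read_csv(p)


def load_reference_database(path, dialect="wide"):
    """Read a locally stored copy of the deposited reference database.

    ``path`` points at a genotype CSV (see
    :func:`strassign.read_genotype_table` for the dialects); locality
    cluster ids are attached from the bundled metadata.
    """
    from .genotype_db import read_genotype_table

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"reference database not found at {path}; the deposited genotype "
            "database (DOI 10.5281/zenodo.3660723) must be downloaded "
            "separately and exported to CSV"
        )
    with resources.as_file(_data_path("acaraya_localities.csv")) as p:
        db = read_genotype_table(path, dialect=dialect, localities_csv=p)
    return db


def threshold_counts(scores=None, threshold_percent=70.0,
                     include_corpses=False):
    """Threshold decisions over the published score table.

    Applies the strict > threshold rule to the published locality- and
    cluster-level scores.  Returns a dict with the number of individuals
    assigned at each level and the number assigned to each cluster among
    those passing the cluster threshold.  By default only the 22
    confiscated individuals are counted (the corpses are reported
    separately in the study).
    """
    df = scores if scores is not None else load_published_assignment_scores()
    if not include_corpses:
        df = df[df["group"] == "confiscated"]
    loc_assigned = int((df["locality_score"] > threshold_percent).sum())
    clu_assigned = int((df["cluster_score"] > threshold_percent).sum())
    passing = df[df["cluster_score"] > threshold_percent]
    per_cluster = passing["best_cluster"].value_counts().to_dict()
    return {
        "n_individuals": int(len(df)),
        "assigned_locality": loc_assigned,
        "assigned_cluster": clu_assigned,
        "assigned_per_cluster": per_cluster,
    }
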
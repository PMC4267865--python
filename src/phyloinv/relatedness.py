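"""Phylogenetic relatedness of aliens to native assemblages.

Two per-alien metrics on the dated tree:

* **PNND** - phylogenetic nearest-neighbour distance: the total
  intervening branch length between the alien and the native taxon it is
  most closely related to;
* **MPD** - mean phylogenetic distance: the mean patristic distance
  between the alien and *all* natives in the reference assemblage.

MPD here is focal-species-vs-set, not the community all-pairs MPD of the
eco-phylo literature.  Both are computed at the country scale (natives =
the whole native flora on the tree) and at the plot scale (natives =
natives co-occurring in the survey plot).  Since min <= mean,
PNND <= MPD for every record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core import DatedTree, normalize_label

__all__ = [
    "pnnd",
    "mpd",
    "country_relatedness",
    "plot_relatedness",
    "PlotFilterReport",
]

NATIVE = "native"


def pnnd(
    tree: DatedTree, alien: str, natives
) -> tuple[float, str, list[str]]:
    """Minimum patristic distance from ``alien`` to any native.

    Returns ``(distance, nearest_native, tied_natives)``; ties are broken
    to the lexicographically smallest label and all argmin labels are
    reported.
    """
    natives = sorted(set(natives))
    if not natives:
        raise ValueError("native set must be non-empty")
    if alien in natives:
        raise ValueError("alien must not be in the native set")
    labels, D = tree.distance_matrix([alien] + natives)
    row = D[0, 1:]
    best = row.min()
    tied = [natives[i] for i in np.flatnonzero(row == best)]
    return float(best), tied[0], tied


def mpd(tree: DatedTree, alien: str, natives) -> float:
    """Mean patristic distance from ``alien`` to every native."""
    natives = sorted(set(natives))
    if not natives:
        raise ValueError("native set must be non-empty")
    if alien in natives:
        raise ValueError("alien must not be in the native set")
    labels, D = tree.distance_matrix([alien] + natives)
    return float(D[0, 1:].mean())


def _match_species(tree: DatedTree, species: pd.DataFrame):
    """Align the species table with the tree tips (normalized labels).

    Returns (table restricted to matched species with a ``tip_label``
    column, list of table species absent from the tree, list of tips
    absent from the table).  Nothing is dropped silently: coverage is
    the caller's to report.
    """
    tips = {normalize_label(lab): lab for lab in tree.tip_labels}
    norm = species["species"].astype(str).map(normalize_label)
    matched = norm.isin(tips)
    out = species.loc[matched].copy()
    out["tip_label"] = norm[matched].map(tips)
    unmatched_species = sorted(species.loc[~matched, "species"].astype(str))
    unmatched_tips = sorted(set(tips.values()) - set(out["tip_label"]))
    return out, unmatched_species, unmatched_tips


def _relatedness_from_matrix(D_row: np.ndarray, native_cols: np.ndarray):
    sub = D_row[native_cols]
    j = int(np.argmin(sub))
    return float(sub[j]), int(native_cols[j]), float(sub.mean())


def country_relatedness(
    tree: DatedTree, species: pd.DataFrame
) -> pd.DataFrame:
    """One record per alien on the tree, natives = all native tips.

    Output columns: species, scale ('country'), pnnd, mpd,
    nearest_native, nearest_tied (bool), invasive, alien_group.
    """
    tab, _, _ = _match_species(tree, species)
    natives = sorted(tab.loc[tab["status"] == NATIVE, "tip_label"])
    aliens = tab.loc[tab["status"] != NATIVE]
    if not natives:
        raise ValueError("no native species present on the tree")
    if len(aliens) == 0:
        return pd.DataFrame(
            columns=[
                "species", "scale", "pnnd", "mpd",
                "nearest_native", "nearest_tied", "invasive", "alien_group",
            ]
        )
    aliens = aliens.sort_values("tip_label")
    labels, D = tree.distance_matrix(
        list(aliens["tip_label"]) + natives
    )
    n_a = len(aliens)
    block = D[:n_a, n_a:]
    native_arr = np.array(natives)
    mins = block.min(axis=1)
    rows = []
    for i, (_, sp) in enumerate(aliens.iterrows()):
        tied = np.flatnonzero(block[i] == mins[i])
        rows.append(
            {
                "species": sp["tip_label"],
                "scale": "country",
                "pnnd": float(mins[i]),
                "mpd": float(block[i].mean()),
                "nearest_native": min(native_arr[tied].tolist()),
                "nearest_tied": bool(tied.size > 1),
                "invasive": int(sp["invasive"]),
                "alien_group": sp["alien_group"],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PlotFilterReport:
    """Accounting of the plot-scale filter (nothing dropped silently)."""

    plots_total: int = 0
    plots_retained: int = 0
    plots_dropped_no_native: int = 0
    plots_dropped_no_alien: int = 0
    unknown_species: list = field(default_factory=list)
    occurrences_unknown: int = 0

    @property
    def plots_dropped(self) -> int:
        return self.plots_dropped_no_native + self.plots_dropped_no_alien

    @property
    def retained_fraction(self) -> float:
        return self.plots_retained / self.plots_total if self.plots_total else 0.0


def plot_relatedness(
    tree: DatedTree, species: pd.DataFrame, plots: pd.DataFrame
) -> tuple[pd.DataFrame, PlotFilterReport]:
    """Per-(alien occurrence, plot) PNND and MPD against plot natives.

    Species present in plots but absent from the tree (or the species
    table) are excluded from that plot's native/alien sets and tallied in
    the report.  Plots that do not retain at least one native and one
    alien after matching are excluded and counted.
    """
    tab, _, _ = _match_species(tree, species)
    info = tab.set_index("species")[
        ["tip_label", "status", "invasive", "alien_group"]
    ]
    known = set(info.index)
    labels, D = tree.distance_matrix()
    col = {lab: i for i, lab in enumerate(labels)}

    report = PlotFilterReport()
    unknown: set = set()
    rows = []
    for (sq, pl), grp in plots.groupby(["square", "plot"], sort=True):
        report.plots_total += 1
        sp = pd.unique(grp["species"].astype(str))
        unk = [s for s in sp if s not in known]
        unknown.update(unk)
        report.occurrences_unknown += len(unk)
        sp = [s for s in sp if s in known]
        sub = info.loc[sp]
        nat = sub.loc[sub["status"] == NATIVE, "tip_label"].to_numpy()
        ali = sub.loc[sub["status"] != NATIVE]
        if nat.size == 0:
            report.plots_dropped_no_native += 1
            continue
        if len(ali) == 0:
            report.plots_dropped_no_alien += 1
            continue
        report.plots_retained += 1
        nat_sorted = np.array(sorted(nat))
        nat_cols_sorted = np.array([col[t] for t in nat_sorted])
        for _, arow in ali.iterrows():
            drow = D[col[arow["tip_label"]]]
            sub_d = drow[nat_cols_sorted]
            best = sub_d.min()
            tied = np.flatnonzero(sub_d == best)
            rows.append(
                {
                    "species": arow["tip_label"],
                    "scale": "plot",
                    "square": sq,
                    "plot": pl,
                    "pnnd": float(best),
                    "mpd": float(sub_d.mean()),
                    "nearest_native": min(nat_sorted[tied].tolist()),
                    "nearest_tied": bool(tied.size > 1),
                    "invasive": int(arow["invasive"]),
                    "alien_group": arow["alien_group"],
                }
            )
    report.unknown_species = sorted(unknown)
    cols = [
        "species", "scale", "square", "plot", "pnnd", "mpd",
        "nearest_native", "nearest_tied", "invasive", "alien_group",
    ]
    return pd.DataFrame(rows, columns=cols), report
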
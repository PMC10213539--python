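"""Variant-preselection panels from sequence-density GWAS results.

Panels built from a genome scan over (imputed) sequence variants:

* Top40k — the lowest-p variant in each consecutive non-overlapping 55-kb
  window, significant or not;
* TopSign — the lowest-p variant per window among those with p <= 1e-6
  (Bonferroni at 0.05 assuming independent chip markers), possibly none;
* ChipPlusSign — TopSign merged with the chip;
* LDTags — tag variants after greedy LD pruning at r^2 > 0.1;
* AllComb — the union of LDTags, Top40k, TopSign and Chip.

The scan itself is a two-stage stand-in: phenotypes pre-adjusted for fixed
and litter effects (optionally via mixed-model solutions), then a
single-marker regression with line fitted as a covariate, pooled across
lines.  Windows tile each chromosome as [0, 55k), [55k, 110k), ...; ties on
p break toward the lower bp for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GenotypeSet

DEFAULT_WINDOW_BP = 55_000
DEFAULT_P_THRESHOLD = 1e-6
DEFAULT_R2_THRESHOLD = 0.1


class PanelError(ValueError):
    pass


@dataclass
class GWASResult:
    """Per-marker association results for one trait."""

    table: pd.DataFrame        # marker, chrom, bp, beta, p
    trait: str
    discovery: str = ""

    def __post_init__(self):
        p = self.table["p"].to_numpy()
        if np.any((p <= 0) | (p > 1)):
            raise PanelError("p-values must lie in (0, 1]")


def run_gwas(geno: GenotypeSet, phenotype: np.ndarray,
             lines: np.ndarray | None = None, trait: str = "trait",
             test_animals=None) -> GWASResult:
    """Single-marker scan of an adjusted phenotype with a line covariate.

    ``phenotype`` must already be adjusted for fixed and litter effects (see
    :func:`adjust_phenotype`).  Line labels are projected out of both the
    phenotype and the dosages (within-line centring), then each marker is
    tested by simple regression; constant markers are excluded from the
    scan.  ``test_animals`` asserts the discovery/test contract: any overlap
    with the scanned animals is an error.
    """
    y = np.asarray(phenotype, float)
    if len(y) != geno.n_animals:
        raise PanelError("phenotype length does not match genotype animals")
    if test_animals is not None:
        overlap = set(map(str, test_animals)) & set(map(str, geno.animal_ids))
        if overlap:
            raise PanelError(
                f"discovery set overlaps test set ({len(overlap)} animals)")
    X = geno.dosages.astype(float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    if lines is None:
        lines = np.zeros(len(y), dtype=object)
    lines = np.asarray(lines, dtype=object)
    # project out line means (equivalently: line as categorical covariate)
    for ln in pd.unique(lines):
        rows = lines == ln
        y[rows] = y[rows] - y[rows].mean()
        X[rows] -= X[rows].mean(axis=0, keepdims=True)
    n = len(y)
    n_lines = len(pd.unique(lines))
    sxx = np.einsum("ij,ij->j", X, X)
    nonconst = sxx > 1e-12
    sxy = y @ X
    beta = np.zeros(geno.n_markers)
    pval = np.ones(geno.n_markers)
    dof = n - n_lines - 1
    if dof <= 0:
        raise PanelError("not enough records for the scan")
    beta[nonconst] = sxy[nonconst] / sxx[nonconst]
    syy = float(y @ y)
    rss = syy - beta[nonconst] ** 2 * sxx[nonconst]
    rss = np.maximum(rss, 1e-300)
    se = np.sqrt(rss / dof / sxx[nonconst])
    tstat = beta[nonconst] / se
    pval[nonconst] = np.minimum(
        np.maximum(2.0 * stats.t.sf(np.abs(tstat), dof), 1e-300), 1.0)
    tab = geno.marker_map[["marker", "chrom", "bp"]].copy()
    tab["beta"] = beta
    tab["p"] = pval
    tab["tested"] = nonconst
    return GWASResult(table=tab[tab["tested"]].drop(columns="tested")
                      .reset_index(drop=True), trait=trait)


def adjust_phenotype(data: pd.DataFrame, trait: str, result=None,
                     fixed: tuple = ("cg",), litter_col: str = "litter"
                     ) -> pd.DataFrame:
    """Phenotypes minus fixed-effect (and litter) estimates for one trait.

    With ``result`` (a solved evaluation) the mixed-model solutions are
    subtracted; otherwise plain within-group centring on the fixed columns.
    Returns a frame (animal, value) over recorded animals.
    """
    rows = data[~pd.isna(data[trait])].copy()
    y = rows[trait].to_numpy(float)
    if result is not None:
        fx = result.fixed(trait)
        adj = np.zeros(len(rows))
        for col in fixed:
            key = rows[col].map(lambda v: f"{col}={v}")
            adj += key.map(fx).fillna(0.0).to_numpy()
        if litter_col in rows.columns and len(result.system.litter_levels):
            t_idx = [t.name for t in result.system.spec.traits].index(trait)
            lit = pd.Series(result.litter()[:, t_idx],
                            index=result.system.litter_levels)
            adj += rows[litter_col].map(lit).fillna(0.0).to_numpy()
        y = y - adj
    else:
        for col in fixed:
            y = y - rows.groupby(col)[trait].transform("mean").to_numpy()
    return pd.DataFrame({"animal": rows["animal"].to_numpy(), "value": y})


def select_top_per_window(gwas: GWASResult, window_bp: int = DEFAULT_WINDOW_BP,
                          mode: str = "top40k",
                          p_threshold: float = DEFAULT_P_THRESHOLD
                          ) -> np.ndarray:
    """Lowest-p marker per non-overlapping window; returns marker ids.

    ``mode='top40k'`` keeps the argmin-p marker of every nonempty window;
    ``mode='topsign'`` only considers markers with p <= ``p_threshold`` and
    may select nothing in a window.
    """
    if mode not in ("top40k", "topsign"):
        raise PanelError(f"unknown window mode {mode!r}")
    if window_bp <= 0:
        raise PanelError("window size must be positive")
    tab = gwas.table.sort_values(["chrom", "bp"], kind="mergesort")
    if mode == "topsign":
        tab = tab[tab["p"] <= p_threshold]
    if tab.empty:
        return np.array([], dtype=object)
    win = tab["bp"].to_numpy() // window_bp
    tab = tab.assign(_win=win)
    # stable sort => ties on p resolve to the lowest bp
    tab = tab.sort_values(["chrom", "_win", "p", "bp"], kind="mergesort")
    sel = tab.groupby(["chrom", "_win"], sort=True).head(1)
    return sel.sort_values(["chrom", "bp"])["marker"].to_numpy()


def ld_prune(geno: GenotypeSet, r2_threshold: float = DEFAULT_R2_THRESHOLD,
             window_bp: int = 1_000_000) -> np.ndarray:
    """Greedy left-to-right LD pruning within chromosome; returns tag ids.

    A marker is kept unless its squared dosage correlation with an
    already-kept marker within ``window_bp`` exceeds the threshold.
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise PanelError("r2 threshold must be in [0, 1]")
    X = geno.dosages.astype(float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    X = X - X.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", X, X))
    keep = []
    mm = geno.marker_map.reset_index(drop=True)
    for _, grp in mm.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        kept_local: list[int] = []
        for pos, j in enumerate(idx):
            if norms[j] == 0:
                continue            # constant marker: nothing to tag
            ok = True
            for kpos in reversed(kept_local):
                if bp[pos] - bp[kpos] > window_bp:
                    break
                k = idx[kpos]
                r = X[:, j] @ X[:, k] / (norms[j] * norms[k])
                if r * r > r2_threshold:
                    ok = False
                    break
            if ok:
                kept_local.append(pos)
                keep.append(j)
    return mm.loc[keep, "marker"].to_numpy()


@dataclass
class Panel:
    """A named, map-sorted marker set with its construction manifest."""

    name: str
    markers: np.ndarray
    parents: tuple = ()
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.markers)

    def manifest(self) -> dict:
        return {"name": self.name, "n_markers": int(len(self.markers)),
                "parents": list(self.parents), "params": dict(self.params)}


def combine_panels(parts: dict, name: str,
                   marker_map: pd.DataFrame | None = None) -> Panel:
    """Deduplicated union of marker sets, sorted by map order if given."""
    sets = [np.asarray(v, dtype=object) for v in parts.values()]
    union = set()
    for s in sets:
        union.update(s.tolist())
    if marker_map is not None:
        order = {mk: i for i, mk in enumerate(marker_map["marker"])}
        unknown = union - set(order)
        if unknown:
            raise PanelError(
                f"{len(unknown)} markers not in the marker map namespace")
        out = np.array(sorted(union, key=order.get), dtype=object)
    else:
        out = np.array(sorted(union), dtype=object)
    return Panel(name=name, markers=out, parents=tuple(parts.keys()))


def build_panels(gwas_by_trait: dict, wgs: GenotypeSet, chip_markers,
                 window_bp: int = DEFAULT_WINDOW_BP,
                 p_threshold: float = DEFAULT_P_THRESHOLD,
                 r2_threshold: float = DEFAULT_R2_THRESHOLD) -> dict:
    """All five preselected panels (plus Chip) from per-trait GWAS results.

    Trait-specific Top40k/TopSign selections are merged across traits, as
    when combining the traits of one multi-trait model.
    """
    chip = np.asarray(chip_markers, dtype=object)
    top40k_parts, topsign_parts = {}, {}
    for trait, gw in gwas_by_trait.items():
        top40k_parts[trait] = select_top_per_window(gw, window_bp, "top40k")
        topsign_parts[trait] = select_top_per_window(gw, window_bp, "topsign",
                                                     p_threshold)
    mm = wgs.marker_map
    top40k = combine_panels(top40k_parts, "Top40k", mm)
    topsign = combine_panels(topsign_parts, "TopSign", mm)
    ldtags = Panel("LDTags", ld_prune(wgs, r2_threshold),
                   params={"r2": r2_threshold})
    chip_panel = Panel("Chip", chip)
    chipplussign = combine_panels(
        {"TopSign": topsign.markers, "Chip": chip}, "ChipPlusSign", mm)
    allcomb = combine_panels(
        {"LDTags": ldtags.markers, "Top40k": top40k.markers,
         "TopSign": topsign.markers, "Chip": chip}, "AllComb", mm)
    return {"Chip": chip_panel, "Top40k": top40k, "TopSign": topsign,
            "ChipPlusSign": chipplussign, "LDTags": ldtags,
            "AllComb": allcomb}
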
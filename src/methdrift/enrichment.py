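"""Region/CGI enrichment, gene-set over-representation, and functional overlap.

Region enrichment uses two-sided Fisher exact tests against the background
probe composition (both enrichment and depletion are reported); pathway
enrichment is a one-sided over-representation test on genes after CpGs are
collapsed to unique gene symbols (the probes-per-gene control). BH
correction is applied within each enrichment family separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from methdrift.core_io import ProbeAnnotation
from methdrift.diffmeth import LocationCatalog, bh_adjust
from methdrift.errors import DomainError, ValidationError

logger = logging.getLogger("methdrift")


@dataclass
class GeneSetAnnotation:
    """Pathway membership, gene flag tables, and the background universe."""

    pathways: dict[str, set[str]]
    universe: set[str]
    flags: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        restricted = {}
        for pid, genes in self.pathways.items():
            inside = set(genes) & self.universe
            if not inside:
                raise ValidationError(f"pathway {pid!r} has no genes in the universe")
            restricted[pid] = inside
        self.pathways = restricted


def read_gene_sets(path, universe: set[str]) -> GeneSetAnnotation:
    """Read 'pathway_id<TAB>comma-separated genes' lines."""
    pathways: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, _, genes = line.partition("\t")
            pathways[pid] = {g.strip() for g in genes.split(",") if g.strip()}
    return GeneSetAnnotation(pathways=pathways, universe=universe)


def _fisher_table(a: int, b: int, c: int, d: int, alternative: str) -> tuple[float, float]:
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p)


def region_enrichment(
    catalog: LocationCatalog,
    annotation: ProbeAnnotation,
    background: list[str],
) -> pd.DataFrame:
    """Two-sided Fisher tests of each dmCpG subset against region classes
    and CGI status over the background probe set."""
    if not background:
        raise DomainError("empty background probe set")
    bg = set(background)
    ann = annotation.frame.set_index("probe_id")
    missing = bg - set(ann.index)
    if missing:
        raise ValidationError(f"background probes missing annotation: {sorted(missing)[:5]}")

    subsets: dict[str, set[str]] = {}
    for name, df in (("u", catalog.u), ("nu", catalog.nu)):
        for direction in ("hyper", "hypo"):
            probes = set(df.loc[df["direction"] == direction, "probe_id"])
            subsets[f"{name}_{direction}"] = probes & bg

    categories = [("region_class", lvl) for lvl in ("promoter", "enhancer", "weak_transcription")]
    categories += [("cgi_status", lvl) for lvl in ("island", "non_island")]

    bg_list = sorted(bg)
    ann_bg = ann.loc[bg_list]
    rows = []
    for set_name, probes in subsets.items():
        in_set = ann_bg.index.isin(probes)
        for column, level in categories:
            in_cat = (ann_bg[column] == level).to_numpy()
            a = int((in_set & in_cat).sum())
            b = int((in_set & ~in_cat).sum())
            c = int((~in_set & in_cat).sum())
            d = int((~in_set & ~in_cat).sum())
            odds, p = _fisher_table(a, b, c, d, alternative="two-sided")
            rows.append(
                {
                    "set": set_name,
                    "category": f"{column}:{level}",
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds,
                    "p": p,
                    "direction": "enriched" if odds > 1 else ("depleted" if odds < 1 else "none"),
                }
            )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def pathway_enrichment(
    genes: set[str], sets: GeneSetAnnotation, cpg_control: str = "collapse"
) -> pd.DataFrame:
    """One-sided over-representation of a gene set against each pathway.

    Input genes outside the universe are dropped (counted in the log);
    duplicate symbols arriving from multiple CpGs collapse to one gene —
    the ``collapse`` reading of probes-per-gene control. A ``resample``
    mode (gene-level null weighted by probes per gene) is reserved but not
    implemented.
    """
    if cpg_control == "resample":
        raise NotImplementedError(
            "probes-per-gene resampling control is a documented alternative "
            "reading; only 'collapse' is implemented"
        )
    if cpg_control != "collapse":
        raise DomainError(f"unknown cpg_control mode {cpg_control!r}")
    genes = set(genes)
    inside = genes & sets.universe
    n_dropped = len(genes) - len(inside)
    if n_dropped:
        logger.warning("pathway_enrichment: %d genes outside the universe dropped", n_dropped)
    if not inside:
        logger.warning("pathway_enrichment: empty gene list after restriction")
        return pd.DataFrame(
            columns=["pathway_id", "a", "b", "c", "d", "odds_ratio", "p", "adj_p", "significant"]
        )
    n_universe = len(sets.universe)
    rows = []
    for pid in sorted(sets.pathways):
        members = sets.pathways[pid]
        a = len(inside & members)
        b = len(inside) - a
        c = len(members) - a
        d = n_universe - a - b - c
        odds, p = _fisher_table(a, b, c, d, alternative="greater")
        rows.append(
            {"pathway_id": pid, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p}
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] < 0.05
    return out


def functional_overlap(
    catalog: LocationCatalog, annotation: ProbeAnnotation
) -> pd.DataFrame:
    """Genes flagged TSG / oncogene / epigenetic_regulator per dmCpG set and
    direction, with the per-gene percent methylation change attached."""
    ann = annotation.frame
    probe_rows = {
        pid: (syms, flags)
        for pid, syms, flags in zip(ann["probe_id"], ann["gene_symbols"], ann["flags"])
    }
    records = []
    for set_name, df in (("u", catalog.u), ("nu", catalog.nu)):
        for _, row in df.iterrows():
            pid = row["probe_id"]
            if pid not in probe_rows:
                continue
            syms, flags = probe_rows[pid]
            for flag in flags:
                for gene in syms:
                    records.append(
                        {
                            "set": set_name,
                            "direction": row["direction"],
                            "flag": flag,
                            "gene": gene,
                            "probe_id": pid,
                            "percent_change": row["percent_change"],
                        }
                    )
    return pd.DataFrame(
        records,
        columns=["set", "direction", "flag", "gene", "probe_id", "percent_change"],
    )
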
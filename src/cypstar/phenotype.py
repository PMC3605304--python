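"""Activity Scores and metaboliser-phenotype prediction.

Two schemes are implemented side by side:

* **Activity Score (AS)** — plain additivity of the per-allele numeric
  activities (2.0 increased, 1.0 normal, 0.5 decreased, 0.0 absent, 1.0
  for unknown), binned as

      AS > 2.0        -> UM (ultra-rapid)
      1.5 <= AS <= 2.0 -> EM (extensive)
      0.5 <= AS <= 1.0 -> IM (intermediate)
      AS = 0.0        -> PM (poor)

  Because every per-allele activity is a multiple of 0.5 there is no bin
  between 0 and 0.5; a score that is not a multiple of 0.5 is a domain
  error.

* **Categorical (microarray-style) rules** — "3 or more functional
  alleles" UM; "2 absent function alleles" PM; "1 or 2 reduced function
  alleles" IM; "1 or 2 functional alleles (incl. increased paired with
  decreased or absent)" EM.  The IM and EM rows overlap for mixed
  normal/reduced pairs; these resolve to EM when the AS is >= 1.5 and IM
  otherwise, and the rule that fired is reported with each call.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .caller import NovelAlleleCandidate
from .catalog import ActivityClass, AlleleCatalog, Gene, activity_of

__all__ = [
    "activity_score",
    "classify_as",
    "classify_amplichip_rules",
    "cohort_phenotype_table",
    "scheme_disagreement_matrix",
    "PHENOTYPE_ORDER",
    "PHENOTYPE_ROWS",
]

PHENOTYPE_ORDER = ["PM", "IM", "EM", "UM"]
PHENOTYPE_ROWS = ["PM", "IM", "EM", "UM", "unknown", "no_call", "failure"]


def _allele_activity(h, gene: Gene, catalog: AlleleCatalog) -> float:
    if isinstance(h, NovelAlleleCandidate):
        return h.assigned_activity
    return activity_of(catalog, gene, h)


def activity_score(diplotype, gene: Gene | str, catalog: AlleleCatalog) -> float:
    """AS of a diplotype: sum of the two per-allele activities."""
    gene = Gene(gene)
    a, b = diplotype
    return _allele_activity(a, gene, catalog) + _allele_activity(b, gene, catalog)


def classify_as(score: float) -> str:
    """Bin an Activity Score into PM/IM/EM/UM."""
    if score < 0 or abs(score * 2 - round(score * 2)) > 1e-9:
        raise ValueError(f"activity score must be a non-negative multiple "
                         f"of 0.5, got {score}")
    if score == 0.0:
        return "PM"
    if score <= 1.0:
        return "IM"
    if score <= 2.0:
        return "EM"
    return "UM"


def _copies(h, gene: Gene, catalog: AlleleCatalog):
    """(copy count, per-copy activity class) for one diplotype member."""
    if isinstance(h, NovelAlleleCandidate):
        cls = (ActivityClass.ABSENT if h.assigned_activity == 0.0
               else ActivityClass.UNKNOWN)
        return 1, cls
    name, copies = h, 1
    if name.endswith("xN"):
        copies = 2
        if (gene, name) in catalog:
            base = catalog.get(gene, name).base_allele
            name = base if base else name[:-2]
        else:
            name = name[:-2]
    allele = catalog.get(gene, name)
    if allele.cnv_multiplier == 0:
        copies = 0
        return copies, ActivityClass.ABSENT
    return copies, allele.activity


def classify_amplichip_rules(diplotype, gene: Gene | str,
                             catalog: AlleleCatalog) -> tuple[str, str]:
    """Categorical phenotype prediction; returns (label, rule_fired).

    Allele copies from xN duplications count individually toward the
    "3 or more functional alleles" rule.  Unknown-class alleles count as
    functional via their default numeric activity of 1.0.
    """
    gene = Gene(gene)
    functional = reduced = absent_members = 0
    for h in diplotype:
        copies, cls = _copies(h, gene, catalog)
        if cls in (ActivityClass.NORMAL, ActivityClass.UNKNOWN,
                   ActivityClass.INCREASED):
            functional += max(copies, 1) if cls is not ActivityClass.INCREASED \
                else max(copies, 2)
        elif cls is ActivityClass.DECREASED:
            reduced += max(copies, 1)
        else:
            absent_members += 1
    if functional >= 3:
        return "UM", "3 or more functional alleles"
    if absent_members == 2:
        return "PM", "2 absent function alleles"
    if reduced and functional:
        # Overlapping rows: mixed normal/reduced pairs.
        score = activity_score(diplotype, gene, catalog)
        if score >= 1.5:
            return "EM", "functional paired with reduced (AS >= 1.5)"
        return "IM", "functional paired with reduced (AS < 1.5)"
    if reduced:
        return "IM", "1 or 2 reduced function alleles"
    return "EM", "1 or 2 functional alleles"


def cohort_phenotype_table(calls, strata: dict[str, str],
                           scheme: str = "activity_score") -> pd.DataFrame:
    """Per-stratum phenotype percentages in the frequency-table layout.

    ``strata`` maps sample_id -> stratum label; rows are
    PM/IM/EM/UM/unknown/no_call/failure and sum to 100 within rounding per
    stratum.  Calls whose sample is missing from ``strata`` are grouped
    under "all".  Empty strata are omitted with a warning.
    """
    if len(calls) == 0:
        raise ValueError("cohort_phenotype_table requires at least one call")
    if scheme not in ("activity_score", "amplichip_rules"):
        raise ValueError(f"unknown scheme {scheme!r}")
    counts: dict[str, dict[str, int]] = {}
    for call in calls:
        stratum = strata.get(call.sample_id, "all")
        label = (call.phenotype if scheme == "activity_score"
                 else call.phenotype_amplichip)
        if label not in PHENOTYPE_ROWS:
            label = "unknown"
        col = counts.setdefault(stratum, {row: 0 for row in PHENOTYPE_ROWS})
        col[label] += 1
    order = [s for s in dict.fromkeys(strata.values()) if s in counts]
    order += [s for s in counts if s not in order]
    missing = set(dict.fromkeys(strata.values())) - set(counts)
    if missing:
        warnings.warn(f"empty strata omitted: {sorted(missing)}",
                      stacklevel=2)
    table = pd.DataFrame(
        {s: {row: 100.0 * counts[s][row] / sum(counts[s].values())
             for row in PHENOTYPE_ROWS}
         for s in order}
    ).reindex(PHENOTYPE_ROWS)
    table.attrs["denominators"] = {s: sum(counts[s].values()) for s in order}
    table.attrs["scheme"] = scheme
    return table


def scheme_disagreement_matrix(calls) -> pd.DataFrame:
    """Cross-tabulation of AS-scheme vs categorical-rule phenotypes.

    The two schemes genuinely disagree on some diplotypes (e.g. a normal
    allele paired with an absent one is EM by the categorical rows but IM
    by AS = 1.0); the matrix quantifies that.
    """
    rows = [(c.phenotype, c.phenotype_amplichip) for c in calls
            if c.phenotype in PHENOTYPE_ORDER]
    matrix = pd.DataFrame(0, index=PHENOTYPE_ORDER, columns=PHENOTYPE_ORDER)
    for as_label, chip_label in rows:
        if chip_label in PHENOTYPE_ORDER:
            matrix.loc[as_label, chip_label] += 1
    matrix.index.name = "activity_score"
    matrix.columns.name = "amplichip_rules"
    return matrix
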
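"""Allele harmonization of exposure/outcome summary-statistic pairs.

Two-sample MR requires both studies' effects to be expressed per copy
of the same allele. Outcome records reported on the swapped allele get
a sign flip; records reported on the opposite strand are complemented
first. Palindromic variants (A/T, C/G) carry no strand information in
their allele labels, so they are oriented by allele frequency when
both studies' frequencies are far enough from 0.5, and dropped
otherwise.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .records import COMPLEMENT, HarmonizedPair

logger = logging.getLogger(__name__)

DEFAULT_PALINDROME_EAF_LIMIT = 0.42


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return COMPLEMENT.get(effect_allele) == other_allele


def _pair(exp: Mapping, out: Mapping, action: str,
          beta_out: float | None = None, eaf_out: float | None = None) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=exp["snp_id"],
        effect_allele=exp["effect_allele"],
        other_allele=exp["other_allele"],
        beta_exposure=float(exp["beta"]),
        se_exposure=float(exp["se"]),
        beta_outcome=float(out["beta"]) if beta_out is None else beta_out,
        se_outcome=float(out["se"]),
        eaf_exposure=None if pd.isna(exp.get("eaf")) else float(exp["eaf"]),
        eaf_outcome=(
            None if (eaf_out is None and pd.isna(out.get("eaf")))
            else float(out["eaf"]) if eaf_out is None else eaf_out
        ),
        action_taken=action,
    )


def _freq_side(eaf: float) -> bool:
    return eaf < 0.5


def harmonize_pair(
    exposure: Mapping,
    outcome: Mapping,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> HarmonizedPair:
    """Express one SNP's outcome effect on the exposure's effect allele.

    Accepts any mapping with the summary-table fields (a dict, a pandas
    row). For palindromic variants both frequencies must lie outside
    ``[limit, 1 - limit]`` to orient the strands; the orientation that
    makes the minor allele agree across studies is chosen. Alleles
    that cannot be reconciled, and unresolvable palindromes, yield a
    ``dropped(<reason>)`` action.
    """
    if exposure["snp_id"] != outcome["snp_id"]:
        raise ValueError(
            f"snp_id mismatch: {exposure['snp_id']!r} vs {outcome['snp_id']!r}"
        )
    ea_e, oa_e = exposure["effect_allele"], exposure["other_allele"]
    ea_o, oa_o = outcome["effect_allele"], outcome["other_allele"]
    valid = set(COMPLEMENT)
    if not ({ea_e, oa_e} <= valid and {ea_o, oa_o} <= valid):
        return _pair(exposure, outcome, "dropped(non_acgt_alleles)")

    beta_o, eaf_o = float(outcome["beta"]), outcome.get("eaf")
    eaf_o = None if pd.isna(eaf_o) else float(eaf_o)
    eaf_e = exposure.get("eaf")
    eaf_e = None if pd.isna(eaf_e) else float(eaf_e)

    if is_palindromic(ea_e, oa_e):
        # labels identify the allele pair but not the strand; orient by
        # minor-allele agreement
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return _pair(exposure, outcome, "dropped(incompatible_alleles)")
        if eaf_e is None or eaf_o is None:
            return _pair(exposure, outcome, "dropped(palindrome_missing_eaf)")
        lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
        if lo <= eaf_e <= hi or lo <= eaf_o <= hi:
            return _pair(exposure, outcome, "dropped(ambiguous_palindrome)")
        if ea_o == ea_e:
            if _freq_side(eaf_e) == _freq_side(eaf_o):
                return _pair(exposure, outcome, "none")
            # frequencies disagree: the outcome was reported on the other
            # strand, where the same label names the opposite allele
            return _pair(exposure, outcome, "strand_flip_and_sign_flip",
                         beta_out=-beta_o, eaf_out=1.0 - eaf_o)
        # swapped labels
        if _freq_side(eaf_e) != _freq_side(eaf_o):
            return _pair(exposure, outcome, "sign_flip",
                         beta_out=-beta_o, eaf_out=1.0 - eaf_o)
        return _pair(exposure, outcome, "strand_flip")

    if {ea_o, oa_o} == {ea_e, oa_e}:
        if ea_o == ea_e:
            return _pair(exposure, outcome, "none")
        return _pair(exposure, outcome, "sign_flip",
                     beta_out=-beta_o,
                     eaf_out=None if eaf_o is None else 1.0 - eaf_o)
    cea, coa = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
    if {cea, coa} == {ea_e, oa_e}:
        if cea == ea_e:
            return _pair(exposure, outcome, "strand_flip")
        return _pair(exposure, outcome, "strand_flip_and_sign_flip",
                     beta_out=-beta_o,
                     eaf_out=None if eaf_o is None else 1.0 - eaf_o)
    return _pair(exposure, outcome, "dropped(incompatible_alleles)")


def harmonize_set(
    instruments: pd.DataFrame,
    outcome_records: pd.DataFrame,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> tuple[list[HarmonizedPair], list[HarmonizedPair]]:
    """Harmonize each instrument against the outcome study.

    Pairs are matched by snp_id; instruments absent from the outcome
    table are reported as dropped(missing_in_outcome). Returns
    ``(kept, dropped)``.
    """
    out_by_id = {r["snp_id"]: r for _, r in outcome_records.iterrows()}
    kept: list[HarmonizedPair] = []
    dropped: list[HarmonizedPair] = []
    for _, exp in instruments.iterrows():
        out = out_by_id.get(exp["snp_id"])
        if out is None:
            dropped.append(_pair(exp, exp, "dropped(missing_in_outcome)"))
            continue
        pair = harmonize_pair(exp, out, palindrome_eaf_limit)
        (dropped if pair.dropped else kept).append(pair)
    if dropped:
        logger.debug(
            "harmonization dropped %d of %d SNPs: %s",
            len(dropped), len(instruments),
            [(p.snp_id, p.action_taken) for p in dropped],
        )
    logger.info("harmonized %d pairs, dropped %d", len(kept), len(dropped))
    return kept, dropped
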
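"""Independent brute-force oracle for the ACMG combining table.

Hand-coded straight from the published table as literal if-clauses, kept
deliberately separate in style and structure from the package's vectorised
implementation so the two can cross-check each other.
"""

from __future__ import annotations

_PS = ("PS1", "PS2", "PS3", "PS4")
_PM = ("PM1", "PM2", "PM3", "PM4", "PM5", "PM6")
_PP = ("PP1", "PP2", "PP3", "PP4", "PP5")
_BS = ("BS1", "BS2", "BS3", "BS4")
_BP = ("BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7")


def _pathogenic(pvs: bool, ps: int, pm: int, pp: int) -> bool:
    if pvs:
        if ps >= 1:
            return True
        if pm >= 2:
            return True
        if pm >= 1 and pp >= 1:
            return True
        if pp >= 2:
            return True
    if ps >= 2:
        return True
    if ps == 1:
        if pm >= 3:
            return True
        if pm >= 2 and pp >= 2:
            return True
        if pm >= 1 and pp >= 4:
            return True
    return False


def _likely_pathogenic(pvs: bool, ps: int, pm: int, pp: int) -> bool:
    if pvs and pm >= 1:
        return True
    if ps == 1 and 1 <= pm <= 2:
        return True
    if ps == 1 and pp >= 2:
        return True
    if pm >= 3:
        return True
    if pm == 2 and pp >= 2:
        return True
    if pm == 1 and pp >= 4:
        return True
    return False


def _benign(ba: bool, bs: int) -> bool:
    return ba or bs >= 2


def _likely_benign(bs: int, bp: int) -> bool:
    if bs == 1 and bp >= 1:
        return True
    return bp >= 2


def oracle_class(active: frozenset[str] | set[str]) -> str:
    """Five-way class for a set of active criterion names."""
    pvs = "PVS1" in active
    ps = sum(c in active for c in _PS)
    pm = sum(c in active for c in _PM)
    pp = sum(c in active for c in _PP)
    ba = "BA1" in active
    bs = sum(c in active for c in _BS)
    bp = sum(c in active for c in _BP)

    any_pathogenic_flag = pvs or ps > 0 or pm > 0 or pp > 0
    benign_side = _benign(ba, bs) or _likely_benign(bs, bp)
    if benign_side and any_pathogenic_flag:
        return "vus"
    if _pathogenic(pvs, ps, pm, pp):
        return "pathogenic"
    if _likely_pathogenic(pvs, ps, pm, pp):
        return "likely_pathogenic"
    if _benign(ba, bs):
        return "benign"
    if _likely_benign(bs, bp):
        return "likely_benign"
    return "vus"
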
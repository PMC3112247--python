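"""Register-vs-truth comparison, error classification and empirical rates.

Comparing a register profile with the consensus re-genotyped ("true")
profile at one locus yields one of four observable error categories:

* ``single_false_allele``  — one allele length mis-recorded, genotype class
  (het/hom) unchanged;
* ``double_false_allele``  — both allele lengths mis-recorded;
* ``false_homozygote``     — a true heterozygote recorded as a homozygote;
* ``false_heterozygote``   — a true homozygote recorded as a heterozygote.

Because allele pairs are unordered, the number of erroneous gene copies at
a locus is the minimum number of substitutions transforming one multiset
into the other (0, 1 or 2), i.e. mismatches are minimized over the two
possible pairings.  Per-allele rates use that count; per-locus rates use
the error indicator.  Under within-locus independence of the two gene
copies the per-locus rate predicted from a per-allele rate ``p_a`` is
``1 - (1 - p_a)^2``.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from . import nmdr
from .profiles import GenotypeProfile

ERROR_CLASSES = ["single_false_allele", "double_false_allele",
                 "false_homozygote", "false_heterozygote"]
SHIFT_CLASSES = ["eq_1bp", "gt_1bp", "mixed", "not_applicable"]


class PairingError(ValueError):
    """Register and truth sets cannot be paired (mismatched individuals/loci)."""


@dataclasses.dataclass(frozen=True)
class ComparisonRecord:
    """Outcome of one individual x locus register-vs-truth comparison."""

    individual_id: str
    year: int
    lab: str
    locus: str
    multiplex: str
    register_gt: tuple[int, int]
    true_gt: tuple[int, int]
    is_error: bool
    error_class: str          # one of ERROR_CLASSES or "none"
    allele_error_count: int   # 0, 1 or 2
    shift_class: str          # eq_1bp / gt_1bp / mixed / not_applicable
    flagged: bool = False     # unusual corner (e.g. het -> novel homozygote)


def _pairings(true_gt: Sequence[int], obs_gt: Sequence[int]):
    """Both alignments of two unordered pairs: list of (n_mismatch, shifts)."""
    (a, b), (c, d) = true_gt, obs_gt
    out = []
    for obs in ((c, d), (d, c)):
        shifts = [abs(a - obs[0]), abs(b - obs[1])]
        mism = [s for s in shifts if s > 0]
        out.append((len(mism), sum(mism), mism))
    return out


def _best_pairing(true_gt, obs_gt):
    """Minimum-substitution alignment; ties broken by smaller total shift."""
    return min(_pairings(true_gt, obs_gt), key=lambda t: (t[0], t[1]))


def _shift_class(shifts: list[int]) -> str:
    if not shifts:
        return "not_applicable"
    if all(s == 1 for s in shifts):
        return "eq_1bp"
    if all(s > 1 for s in shifts):
        return "gt_1bp"
    return "mixed"


def classify_error(true_gt: tuple[int, int],
                   obs_gt: tuple[int, int]) -> tuple[str, int, str]:
    """Classify a discordant genotype pair.

    Returns ``(error_class, allele_error_count, shift_class)``.  Genotype-
    class transitions (het<->hom) take precedence; within a class the count
    of shifted alleles decides between single and double false allele size.
    Raises ``ValueError`` when the pairs are equal (no error to classify).
    """
    true_gt = tuple(sorted(true_gt))
    obs_gt = tuple(sorted(obs_gt))
    if true_gt == obs_gt:
        raise ValueError("classify_error requires discordant genotypes")
    true_hom = true_gt[0] == true_gt[1]
    obs_hom = obs_gt[0] == obs_gt[1]
    n_err, _, shifts = _best_pairing(true_gt, obs_gt)
    if not true_hom and obs_hom:
        # het recorded as hom; usually hom of one true allele (count 1).
        return "false_homozygote", n_err, _shift_class(shifts)
    if true_hom and not obs_hom:
        if true_gt[0] in obs_gt:
            return "false_heterozygote", n_err, _shift_class(shifts)
        return "double_false_allele", n_err, _shift_class(shifts)
    if n_err == 1:
        return "single_false_allele", 1, _shift_class(shifts)
    return "double_false_allele", n_err, _shift_class(shifts)


def compare_profiles(register: Iterable[GenotypeProfile],
                     truth: Iterable[GenotypeProfile]) -> list[ComparisonRecord]:
    """Pair register and truth profiles by individual and compare per locus.

    Year, lab and multiplex metadata are taken from the truth profile.
    Raises :class:`PairingError` when the individual sets differ or an
    individual's locus sets differ between the two profiles.
    """
    reg = {p.individual_id: p for p in register}
    tru = {p.individual_id: p for p in truth}
    if set(reg) != set(tru):
        only = set(reg) ^ set(tru)
        raise PairingError(f"unpaired individual(s): {sorted(only)[:5]}")
    records = []
    for ind in sorted(tru):
        r, t = reg[ind], tru[ind]
        if set(r.genotypes) != set(t.genotypes):
            raise PairingError(f"{ind}: locus sets differ between register and truth")
        for locus in sorted(t.genotypes):
            tg, og = t.genotypes[locus], r.genotypes[locus]
            if tg == og:
                records.append(ComparisonRecord(
                    ind, t.year, t.lab, locus, t.multiplex_of[locus],
                    og, tg, False, "none", 0, "not_applicable"))
            else:
                cls, cnt, shift = classify_error(tg, og)
                flagged = cls == "false_homozygote" and cnt == 2
                records.append(ComparisonRecord(
                    ind, t.year, t.lab, locus, t.multiplex_of[locus],
                    og, tg, True, cls, cnt, shift, flagged))
    return records


def tally_errors(records: Iterable[ComparisonRecord],
                 labs: Sequence[str] | None = None) -> pd.DataFrame:
    """Error counts per lab x class, split by bp-shift class.

    Columns: ``lab, error_class, total, eq_1bp, gt_1bp, mixed`` plus a
    grand-total row per class (lab = "Total").
    """
    records = list(records)
    if labs is None:
        labs = sorted({r.lab for r in records})
    counts: Counter = Counter()
    for r in records:
        if r.is_error:
            counts[(r.lab, r.error_class, r.shift_class)] += 1
    rows = []
    for lab in list(labs) + ["Total"]:
        for cls in ERROR_CLASSES:
            if lab == "Total":
                sub = {s: sum(counts[(l, cls, s)] for l in labs)
                       for s in SHIFT_CLASSES}
            else:
                sub = {s: counts[(lab, cls, s)] for s in SHIFT_CLASSES}
            rows.append((lab, cls, sum(sub.values()),
                         sub["eq_1bp"], sub["gt_1bp"], sub["mixed"]))
    return pd.DataFrame(rows, columns=["lab", "error_class", "total",
                                       "eq_1bp", "gt_1bp", "mixed"])


def predict_pl_from_pa(p_a: float) -> float:
    """Per-locus error rate implied by a per-allele rate when the two gene
    copies err independently: ``1 - (1 - p_a)^2``."""
    if not 0.0 <= p_a <= 1.0:
        raise ValueError(f"p_a must be in [0, 1], got {p_a}")
    return 1.0 - (1.0 - p_a) ** 2


def _binomial_sd(p: float, m: int) -> float:
    return math.sqrt(p * (1.0 - p) / m) if m > 0 else float("nan")


def empirical_rates(records: Iterable[ComparisonRecord],
                    grouping: str = "lab") -> pd.DataFrame:
    """Empirical per-locus and per-allele error rates with binomial SDs.

    ``grouping`` is one of ``"lab"``, ``"year"``, ``"locus"`` or
    ``"total"``.  For each group with ``n`` individuals genotyped at ``L``
    loci, ``p_l`` = errors / (nL) with SD sqrt(p(1-p)/(nL)) and
    ``p_a`` = allele errors / (2nL) with SD sqrt(p(1-p)/(2nL)); ``pred`` is
    the independence prediction of ``p_l`` from ``p_a``.  A "Total" row is
    always appended.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no comparison records")
    frame = pd.DataFrame({
        "individual_id": [r.individual_id for r in recs],
        "lab": [r.lab for r in recs],
        "year": [r.year for r in recs],
        "locus": [r.locus for r in recs],
        "is_error": [r.is_error for r in recs],
        "allele_errors": [r.allele_error_count for r in recs],
    })

    def one_group(name, grp: pd.DataFrame):
        n = grp["individual_id"].nunique()
        m = len(grp)          # locus observations
        p_l = grp["is_error"].sum() / m
        p_a = grp["allele_errors"].sum() / (2 * m)
        return {
            "group": name, "n": n, "locus_obs": m, "allele_obs": 2 * m,
            "p_l": p_l, "sd_pl": _binomial_sd(p_l, m),
            "p_a": p_a, "sd_pa": _binomial_sd(p_a, 2 * m),
            "pred": predict_pl_from_pa(p_a),
        }

    rows = []
    if grouping != "total":
        if grouping not in ("lab", "year", "locus"):
            raise ValueError(f"unknown grouping {grouping!r}")
        for name, grp in frame.groupby(grouping, sort=True):
            rows.append(one_group(name, grp))
    rows.append(one_group("Total", frame))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reconstruction of comparison records from a published-style tally
# ---------------------------------------------------------------------------

_CANONICAL_GENOTYPES = {
    # (class, shift) -> (true genotype, observed genotype)
    ("single_false_allele", "eq_1bp"): ((150, 154), (150, 155)),
    ("single_false_allele", "gt_1bp"): ((150, 154), (150, 158)),
    ("double_false_allele", "eq_1bp"): ((150, 154), (151, 155)),
    ("double_false_allele", "gt_1bp"): ((150, 154), (152, 158)),
    ("false_homozygote", "eq_1bp"): ((150, 151), (150, 150)),
    ("false_homozygote", "gt_1bp"): ((150, 154), (150, 150)),
    ("false_heterozygote", "eq_1bp"): ((150, 150), (150, 151)),
    ("false_heterozygote", "gt_1bp"): ((150, 150), (150, 152)),
}


def records_from_tally(tally: dict[str, dict[str, tuple[int, int]]] | None = None,
                       n_by_lab: dict[str, int] | None = None,
                       loci: Sequence[str] | None = None) -> list[ComparisonRecord]:
    """Build a comparison-record set realizing a per-lab error tally.

    Given counts of each error class split into 1-bp and >1-bp shifts (the
    NMDR audit tally by default) and per-lab sample sizes, constructs one
    record per individual x locus in which exactly the tallied errors occur,
    each with a canonical genotype pair reproducing its class and shift.
    Errors are spread round-robin over distinct individuals and over the
    non-error-free loci so every retained locus carries events.  The
    resulting records reproduce the audit's empirical rate table exactly.
    """
    if tally is None:
        tally = nmdr.ERROR_TALLY
    if n_by_lab is None:
        n_by_lab = nmdr.SAMPLES_PER_LAB
    if loci is None:
        loci = nmdr.LOCI
    error_loci = [l for l in loci if l not in nmdr.ERROR_FREE_LOCI]

    # assign catch years within each lab's period, round-robin
    years_of_lab: dict[str, list[int]] = {}
    for year, lab in nmdr.LAB_OF_YEAR.items():
        years_of_lab.setdefault(lab, []).append(year)

    records: list[ComparisonRecord] = []
    for lab in sorted(n_by_lab):
        n = n_by_lab[lab]
        years = sorted(years_of_lab.get(lab, [nmdr.CENTER_YEAR]))
        # error slots: (individual index, locus index) spread out
        slots = []
        for cls in ERROR_CLASSES:
            eq1, gt1 = tally.get(lab, {}).get(cls, (0, 0))
            slots += [(cls, "eq_1bp")] * eq1 + [(cls, "gt_1bp")] * gt1
        if len(slots) > n * len(error_loci):
            raise ValueError(f"{lab}: more errors than observation slots")
        error_at: dict[tuple[int, str], tuple[str, str]] = {}
        for k, slot in enumerate(slots):
            i, locus = k % n, error_loci[k % len(error_loci)]
            while (i, locus) in error_at:   # linear probing over individuals
                i = (i + 1) % n
            error_at[(i, locus)] = slot
        for i in range(n):
            ind = f"{lab}_ind{i:03d}"
            year = years[i % len(years)]
            for locus in loci:
                mp = nmdr.MULTIPLEXES.get(locus, "mp1")
                if (i, locus) in error_at:
                    cls, shift = error_at[(i, locus)]
                    tg, og = _CANONICAL_GENOTYPES[(cls, shift)]
                    cnt = 2 if cls == "double_false_allele" else 1
                    records.append(ComparisonRecord(
                        ind, year, lab, locus, mp, og, tg, True, cls, cnt, shift))
                else:
                    records.append(ComparisonRecord(
                        ind, year, lab, locus, mp, (150, 154), (150, 154),
                        False, "none", 0, "not_applicable"))
    return records
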
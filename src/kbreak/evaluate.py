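"""Category-wise sensitivity and precision against simulator ground truth.

Two levels are scored separately:

* *mapping*: per category of reads (carrying an SNV, insertion, deletion,
  splice junction, sequencing error, or chimeric junction), the fraction
  reported at a unique and correct genomic location (correct = same
  chromosome and strand, position within a small tolerance of the true
  origin at the reported read offset);
* *events*: per category of distinct events, predictions matched one-to-
  one against planted truth — SNVs and indels at exact position and size,
  splice and chimeric junctions with a +/-3 nt tolerance on both anchors.

Sensitivity = TP/(TP+FN), precision = TP/(TP+FP), always over events or
reads of the category, never over covering reads of an event.
"""

from __future__ import annotations

import pandas as pd

from .classify import EventCandidate, ReadAnnotation
from .simulate import TruthLedger

MAPPING_CATEGORIES = ["snv", "insertion", "deletion", "splice", "error", "chimera", "none"]
EVENT_CATEGORIES = ["snv", "insertion", "deletion", "indel", "splice", "chimera", "error"]


def _metrics_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["category", "tp", "fp", "fn", "sensitivity", "precision"])
    return df.set_index("category")


def read_categories(truth) -> set[str]:
    """Event categories carried by one simulated read."""
    cats = {key[0] for key, _ in truth.events}
    if truth.error_read_pos:
        cats.add("error")
    if not cats:
        cats.add("none")
    return cats


def evaluate_mapping(
    annotations: list[ReadAnnotation],
    ledger: TruthLedger,
    tolerance: int = 5,
) -> pd.DataFrame:
    """Read-mapping sensitivity/precision per read category.

    A read scores as TP when reported ``unique`` with the correct
    chromosome, strand, and a position within ``tolerance`` nt of its true
    origin; uniquely mapped reads at a wrong location count against
    precision, all other reads of the category against sensitivity.
    """
    counts = {c: [0, 0, 0] for c in MAPPING_CATEGORIES}  # n, unique, correct
    for ann in annotations:
        truth = ledger.reads.get(ann.read_id)
        if truth is None:
            raise ValueError(f"read {ann.read_id!r} missing from the truth ledger")
        cats = read_categories(truth)
        unique = ann.status == "unique" and ann.primary is not None
        ok = False
        if unique:
            r, chrom, strand, fwd = ann.primary
            # identical sequence across a junction lets flanking k-mers
            # slide a few bases past the true boundary, shifting the anchor
            # to an equivalent alignment; segments are therefore allowed to
            # extrapolate by the tolerance when matching
            for r0, rl, t_chrom, gs, f0 in truth.segments:
                if gs == 0 or t_chrom != chrom or gs != strand:
                    continue
                if r0 - tolerance <= r <= r0 + rl - 1 + tolerance:
                    if abs(f0 + gs * (r - r0) - fwd) <= tolerance:
                        ok = True
                        break
        for c in cats:
            counts[c][0] += 1
            if unique:
                counts[c][1] += 1
                if ok:
                    counts[c][2] += 1
    rows = []
    for c in MAPPING_CATEGORIES:
        n, uniq, correct = counts[c]
        rows.append(
            {
                "category": c,
                "tp": correct,
                "fp": uniq - correct,
                "fn": n - correct,
                "sensitivity": correct / n if n else float("nan"),
                "precision": correct / uniq if uniq else float("nan"),
            }
        )
    return _metrics_frame(rows)


def _truth_events(ledger: TruthLedger) -> dict[str, list[tuple]]:
    truth: dict[str, list[tuple]] = {c: [] for c in EVENT_CATEGORIES if c != "indel"}
    for v in ledger.variants:
        truth[v.kind].append(v.key)
    truth["splice"] = list(dict.fromkeys(ledger.junctions))
    truth["chimera"] = [f.key for f in ledger.fusions]
    err = set()
    for rt in ledger.reads.values():
        err.update(("error", chrom, pos) for chrom, pos in rt.error_refs)
    truth["error"] = sorted(err)
    return truth


def _coverage(ledger: TruthLedger, min_flank: int = 1) -> dict[tuple, int]:
    cov: dict[tuple, int] = {}
    for rt in ledger.reads.values():
        for key, flank in rt.events:
            if flank >= min_flank:
                cov[key] = cov.get(key, 0) + 1
    return cov


def _match_tolerant(pred_keys: list[tuple], truth_keys: list[tuple], tol: int) -> int:
    """Greedy one-to-one matching of junction-like keys with positional
    tolerance on both anchors; returns the number of matches."""
    unmatched = list(truth_keys)
    tp = 0
    for pk in pred_keys:
        best = None
        for i, tk in enumerate(unmatched):
            if _keys_close(pk, tk, tol):
                best = i
                break
        if best is not None:
            unmatched.pop(best)
            tp += 1
    return tp


def _keys_close(a: tuple, b: tuple, tol: int) -> bool:
    if a[0] != b[0]:
        return False
    if a[0] == "splice":
        return a[1] == b[1] and abs(a[2] - b[2]) <= tol and abs(a[3] - b[3]) <= tol
    # chimera: ("chimera", (chrom,strand,pos), (chrom,strand,pos)); the key
    # is orientation-normalized but tolerance shifts may flip the ordering,
    # so compare both ways
    (a1, a2), (b1, b2) = a[1:3], b[1:3]

    def close(x, y):
        return x[0] == y[0] and x[1] == y[1] and abs(x[2] - y[2]) <= tol

    if close(a1, b1) and close(a2, b2):
        return True
    fa1 = (a2[0], -a2[1], a2[2])
    fa2 = (a1[0], -a1[1], a1[2])
    return close(fa1, b1) and close(fa2, b2)


def evaluate_events(
    candidates: list[EventCandidate],
    ledger: TruthLedger,
    junction_tolerance: int = 3,
    attainable: bool = False,
) -> pd.DataFrame:
    """Event-level TP/FP/FN per category.

    SNVs and indels must match a planted variant exactly (position and
    size); splice and chimeric junctions match within
    ``junction_tolerance`` nt on both anchors; sequencing errors match the
    exact reference position.  With ``attainable`` the FN denominator
    excludes planted events covered by no read.
    """
    truth = _truth_events(ledger)
    cov = _coverage(ledger) if attainable else None
    preds: dict[str, list[tuple]] = {c: [] for c in truth}
    for cand in candidates:
        if cand.kind in preds:
            preds[cand.kind].append(cand.key)
    rows = []
    per_cat: dict[str, tuple[int, int, int]] = {}
    for cat in truth:
        tkeys = truth[cat]
        if cov is not None and cat != "error":
            tkeys = [k for k in tkeys if cov.get(k, 0) > 0]
        pkeys = preds[cat]
        if cat in ("splice", "chimera"):
            tp = _match_tolerant(pkeys, tkeys, junction_tolerance)
        else:
            tset = set(tkeys)
            tp = sum(1 for k in pkeys if k in tset)
        fp = len(pkeys) - tp
        fn = len(tkeys) - tp
        per_cat[cat] = (tp, fp, fn)
    # pooled short-indel category
    ins, dele = per_cat["insertion"], per_cat["deletion"]
    per_cat["indel"] = tuple(x + y for x, y in zip(ins, dele))
    for cat in EVENT_CATEGORIES:
        tp, fp, fn = per_cat[cat]
        rows.append(
            {
                "category": cat,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
            }
        )
    return _metrics_frame(rows)
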
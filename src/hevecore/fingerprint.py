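"""SNP fingerprint codes for variety identification.

A fingerprint assigns each accession a digit string — one character per
selected SNP, '0'/'1'/'2' for the coded genotype and '9' for a missing
call — compact enough to print or pack into a QR code.  Locus selection
is greedy: seed with the highest-PIC locus, then repeatedly add the
locus that resolves the most sample pairs still sharing an identical
partial code (ties prefer higher PIC, then panel order), stopping once
every pair is resolved or the size cap is reached.

Missing-data policy for collision detection is strict by default: a '9'
matches nothing, so two codes differing only at a missing digit count as
distinguished.  The lenient alternative treats '9' as a wildcard.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .divstats import locus_table
from .genotype_io import MISSING, GenotypePanel


@dataclass
class Fingerprint:
    """Selected loci, per-sample codes and QR payloads."""

    locus_ids: list[str]
    codes: "pd.Series"  # index: sample id, value: digit string
    n_unresolved_pairs: int

    def qr_payloads(self) -> pd.Series:
        return pd.Series(
            {s: qr_payload(s, c) for s, c in self.codes.items()}, name="payload"
        )


def select_fingerprint_loci(
    panel: GenotypePanel, n_max: int = 20
) -> tuple[list[str], int]:
    """Greedy highly-discriminating locus subset.

    Returns the selected locus ids in selection order and the residual
    count of sample pairs whose codes remain identical.
    """
    if panel.n_loci < 1:
        raise ValueError("panel has no loci")
    stats = locus_table(panel)
    pic_by_idx = stats["pic"].fillna(-1.0).to_numpy()
    order = np.arange(panel.n_loci)
    # candidate priority for tie-breaks: higher PIC first, then panel order
    priority = sorted(order, key=lambda j: (-pic_by_idx[j], j))

    n = panel.n_samples
    groups: list[np.ndarray] = [np.arange(n)]
    selected: list[int] = []
    unresolved = n * (n - 1) // 2

    while len(selected) < n_max and unresolved > 0:
        best_j = None
        best_unresolved = unresolved
        for j in priority:
            if j in selected:
                continue
            u = _unresolved_after(groups, panel.G[:, j])
            if u < best_unresolved:
                best_unresolved = u
                best_j = j
        if best_j is None:
            if not selected:
                # nothing separates anyone; still emit the top-PIC locus
                best_j = priority[0]
                best_unresolved = unresolved
            else:
                break  # no remaining locus reduces collisions
        selected.append(best_j)
        groups = _split_groups(groups, panel.G[:, best_j])
        unresolved = best_unresolved
    return [panel.locus_ids[j] for j in selected], unresolved


def _split_groups(groups: list[np.ndarray], column: np.ndarray) -> list[np.ndarray]:
    out = []
    for g in groups:
        if len(g) == 1:
            out.append(g)
            continue
        codes = column[g]
        for value in np.unique(codes):
            out.append(g[codes == value])
    return out


def _unresolved_after(groups: list[np.ndarray], column: np.ndarray) -> int:
    total = 0
    for g in groups:
        if len(g) == 1:
            continue
        _, counts = np.unique(column[g], return_counts=True)
        total += int((counts * (counts - 1) // 2).sum())
    return total


def encode_codes(panel: GenotypePanel, locus_ids: list[str]) -> pd.Series:
    """Concatenate coded genotypes into one digit string per sample."""
    pos = {lid: j for j, lid in enumerate(panel.locus_ids)}
    unknown = [lid for lid in locus_ids if lid not in pos]
    if unknown:
        raise KeyError(f"unknown locus ids {unknown}")
    cols = [pos[lid] for lid in locus_ids]
    sub = panel.G[:, cols]
    codes = ["".join(str(int(v)) for v in row) for row in sub]
    return pd.Series(codes, index=pd.Index(panel.sample_ids, name="sample"),
                     name="code")


def distinguishability(
    codes: pd.Series | dict, strict: bool = True
) -> tuple[int, list[set]]:
    """Count sample pairs with indistinguishable codes.

    Strict mode treats '9' as an ordinary character (a missing digit
    distinguishes from a called one); lenient mode lets '9' match any
    digit.  Returns the pair count and the list of colliding id sets.
    """
    items = list(codes.items())
    lengths = {len(c) for _, c in items}
    if len(lengths) > 1:
        raise ValueError(f"ragged code lengths {sorted(lengths)}")
    colliding: list[set] = []
    n_pairs = 0
    if strict:
        by_code: dict[str, list] = {}
        for sid, code in items:
            by_code.setdefault(code, []).append(sid)
        for ids in by_code.values():
            if len(ids) > 1:
                colliding.append(set(ids))
                n_pairs += len(ids) * (len(ids) - 1) // 2
    else:
        pair_sets: dict = {}
        for (sa, ca), (sb, cb) in combinations(items, 2):
            if all(x == y or x == "9" or y == "9" for x, y in zip(ca, cb)):
                n_pairs += 1
                merged = None
                for s in pair_sets.values():
                    if sa in s or sb in s:
                        merged = s
                        break
                if merged is None:
                    pair_sets[len(pair_sets)] = {sa, sb}
                else:
                    merged.update({sa, sb})
        colliding = list(pair_sets.values())
    return n_pairs, colliding


def qr_payload(sample_id: str, code: str) -> str:
    """Plain 'id|code' payload carried by a fingerprint QR code."""
    if not sample_id:
        raise ValueError("empty sample id")
    if "|" in sample_id:
        raise ValueError("sample id must not contain the '|' delimiter")
    if not set(code) <= set("0129"):
        raise ValueError("code characters must be 0/1/2/9")
    return f"{sample_id}|{code}"


def parse_qr_payload(payload: str) -> tuple[str, str]:
    sample_id, _, code = payload.partition("|")
    if not sample_id or not code:
        raise ValueError(f"malformed payload {payload!r}")
    return sample_id, code


def render_qr_png(payload: str, path: str | Path) -> None:
    """Render a payload as a QR PNG (requires the optional ``qrcode`` package)."""
    try:
        import qrcode
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "QR image rendering needs the optional 'qrcode' package; "
            "the payload string itself is the portable artifact"
        ) from exc
    qrcode.make(payload).save(str(path))  # pragma: no cover


def heatmap_matrix(panel: GenotypePanel, locus_ids: list[str]) -> pd.DataFrame:
    """Samples x selected-loci coded matrix (9 = missing) for heatmap export."""
    pos = {lid: j for j, lid in enumerate(panel.locus_ids)}
    unknown = [lid for lid in locus_ids if lid not in pos]
    if unknown:
        raise KeyError(f"unknown locus ids {unknown}")
    cols = [pos[lid] for lid in locus_ids]
    return pd.DataFrame(
        panel.G[:, cols],
        index=pd.Index(panel.sample_ids, name="sample"),
        columns=locus_ids,
    )


def build_fingerprint(
    panel: GenotypePanel, n_max: int = 20, strict: bool = True
) -> Fingerprint:
    """Select loci, encode codes, and audit distinguishability in one call."""
    loci, _ = select_fingerprint_loci(panel, n_max=n_max)
    codes = encode_codes(panel, loci)
    n_pairs, _ = distinguishability(codes, strict=strict)
    return Fingerprint(loci, codes, n_pairs)
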
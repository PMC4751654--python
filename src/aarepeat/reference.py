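"""Straightforward reference implementation of the repeat detector.

``brute_force_detect`` enumerates every candidate interval of a sequence,
checks each repeat invariant directly on the interval, keeps the intervals
maximal under inclusion per main residue and applies the same
one-annotation-per-tract reduction rule as the production detector.

It is deliberately naive -- no barrier decomposition, no sweep tricks -- so
it can serve as an independent cross-check of
:func:`aarepeat.repeat_detection.detect_repeats` on small sequences.
"""

from __future__ import annotations

from .repeat_detection import DetectorParams, RepeatAnnotation, _PURITY_EPS


def _interval_valid(
    sequence: str, residue: str, start: int, end: int, params: DetectorParams
) -> bool:
    window = sequence[start:end]
    if not window or window[0] != residue or window[-1] != residue:
        return False
    main = window.count(residue)
    if len(window) < params.min_core_length:
        return False
    if main < params.min_main_fraction * len(window) - _PURITY_EPS:
        return False
    run = longest = 0
    gap = max_gap = 0
    for ch in window:
        if ch == residue:
            run += 1
            gap = 0
        else:
            gap += 1
            run = 0
        longest = max(longest, run)
        max_gap = max(max_gap, gap)
    if longest < params.min_core_length:
        return False
    if max_gap > params.max_nonmain_run:
        return False
    return True


def brute_force_detect(
    sequence: str,
    params: DetectorParams = DetectorParams(),
    protein_id: str = "",
) -> list[RepeatAnnotation]:
    n = len(sequence)
    residues = sorted({ch for ch in sequence if ch not in ("X", "*")})
    annotations: list[RepeatAnnotation] = []
    for residue in residues:
        # a valid interval needs an uninterrupted core somewhere
        if residue * params.min_core_length not in sequence:
            continue
        valid = [
            (i, j)
            for i in range(n)
            for j in range(i + params.min_core_length, n + 1)
            if _interval_valid(sequence, residue, i, j, params)
        ]
        maximal = [
            iv
            for iv in valid
            if not any(
                o != iv and o[0] <= iv[0] and o[1] >= iv[1] for o in valid
            )
        ]
        # one annotation per tract: longest first (tie left-most), drop any
        # interval overlapping or touching an already kept one
        kept: list[tuple[int, int]] = []
        for iv in sorted(maximal, key=lambda iv: (iv[0] - iv[1], iv[0])):
            if not any(iv[1] >= k[0] and iv[0] <= k[1] for k in kept):
                kept.append(iv)
        for start, end in sorted(kept):
            window = sequence[start:end]
            run = longest = 0
            for ch in window:
                run = run + 1 if ch == residue else 0
                longest = max(longest, run)
            annotations.append(
                RepeatAnnotation(
                    protein_id, residue, start, end, window.count(residue), longest
                )
            )
    annotations.sort(key=lambda a: (a.start, a.main_residue))
    return annotations
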
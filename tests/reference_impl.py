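"""Naive clause-by-clause reference counters used as independent oracles.

Each function re-derives its score from the written rules with straightforward
(quadratic, list-rebuilding) logic, deliberately sharing no code with the
package's counters. Tie-break conventions (major-state ordering, smoothing
removal order) follow the package's documented choices — those are part of the
rule set, not of the implementation under test.
"""

from __future__ import annotations

from scarsig import GenomeAnnotation, SegmentProfile, is_sex_chromosome


def _chrom_segs(profile: SegmentProfile, chrom: str):
    return sorted(
        (s for s in profile.segments if s.chrom == chrom), key=lambda s: s.start
    )


def _merged(profile: SegmentProfile, chrom: str):
    """Canonicalize by re-scanning until no abutting equal-state pair remains."""
    segs = [[s.start, s.end, s.n_major, s.n_minor] for s in _chrom_segs(profile, chrom)]
    done = False
    while not done:
        done = True
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if a[1] == b[0] and a[2:] == b[2:]:
                segs[i] = [a[0], b[1], a[2], a[3]]
                del segs[i + 1]
                done = False
                break
    return segs


def _autosomes(profile: SegmentProfile):
    seen = []
    for s in profile.segments:
        if not is_sex_chromosome(s.chrom) and s.chrom not in seen:
            seen.append(s.chrom)
    return seen


def ref_major_state(profile: SegmentProfile, chrom: str):
    lengths: dict[tuple[int, int], int] = {}
    for start, end, nmaj, nmin in _merged(profile, chrom):
        if nmaj + nmin > 0:
            lengths[(nmaj, nmin)] = lengths.get((nmaj, nmin), 0) + (end - start)
    if not lengths:
        return None
    best = None
    for state, length in lengths.items():
        if best is None:
            best = state
            continue
        b_len = lengths[best]
        if length > b_len:
            best = state
        elif length == b_len:
            if sum(state) < sum(best) or (sum(state) == sum(best) and state[0] < best[0]):
                best = state
    return best


def ref_ntai(profile: SegmentProfile, annotation: GenomeAnnotation) -> int:
    count = 0
    for chrom in _autosomes(profile):
        segs = _merged(profile, chrom)
        info = annotation[chrom]
        major = ref_major_state(profile, chrom)
        outer_p = min(s[0] for s in segs)
        outer_q = max(s[1] for s in segs)
        for start, end, nmaj, nmin in segs:
            terminal_p = start == outer_p and end <= info.centromere_start
            terminal_q = end == outer_q and start >= info.centromere_end
            if not (terminal_p or terminal_q):
                continue
            if nmaj == nmin:
                continue
            if major is not None and (nmaj, nmin) == major:
                continue
            count += 1
    return count


def ref_smooth_arm(segs, min_keep):
    """Fixed-point smoothing, rebuilt from scratch each pass (shortest-first)."""
    segs = [list(s) for s in segs]
    while True:
        short = [s for s in segs if s[1] - s[0] < min_keep]
        if not short:
            return segs
        victim = sorted(short, key=lambda s: (s[1] - s[0], s[0]))[0]
        i = segs.index(victim)
        left = segs[i - 1] if i > 0 else None
        right = segs[i + 1] if i + 1 < len(segs) else None
        segs = segs[:i] + segs[i + 1:]
        if left is not None and right is not None and left[2:] == right[2:]:
            joined = [left[0], right[1], left[2], left[3]]
            j = segs.index(left)
            segs = segs[:j] + [joined] + segs[j + 2:]


def ref_lst(
    profile: SegmentProfile,
    annotation: GenomeAnnotation,
    min_flank=10_000_000,
    min_keep=3_000_000,
    max_gap=3_000_000,
) -> int:
    count = 0
    for chrom in _autosomes(profile):
        info = annotation[chrom]
        for lo, hi in (info.p_arm, info.q_arm):
            clipped = []
            for start, end, nmaj, nmin in _merged(profile, chrom):
                s, e = max(start, lo), min(end, hi)
                if s < e:
                    clipped.append([s, e, nmaj, nmin])
            segs = ref_smooth_arm(clipped, min_keep)
            for i in range(len(segs)):
                for j in range(len(segs)):
                    if j != i + 1:
                        continue
                    a, b = segs[i], segs[j]
                    if a[2:] == b[2:]:
                        continue
                    if a[1] - a[0] < min_flank or b[1] - b[0] < min_flank:
                        continue
                    if b[0] - a[1] >= max_gap:
                        continue
                    count += 1
    return count


def ref_hrd_loh(
    profile: SegmentProfile,
    annotation: GenomeAnnotation,
    min_len=15_000_000,
    exclude=(),
) -> int:
    count = 0
    for chrom in _autosomes(profile):
        if chrom in exclude:
            continue
        segs = _merged(profile, chrom)
        flags = [nmaj >= 1 and nmin == 0 for _, _, nmaj, nmin in segs]
        covered_start = min(s[0] for s in segs)
        covered_end = max(s[1] for s in segs)
        i = 0
        while i < len(segs):
            if not flags[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < len(segs)
                and flags[j + 1]
                and segs[j + 1][0] == segs[j][1]
            ):
                j += 1
            start, end = segs[i][0], segs[j][1]
            whole = start == covered_start and end == covered_end
            if end - start > min_len and not whole:
                count += 1
            i = j + 1
    return count
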
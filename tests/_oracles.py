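"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive re-derivations from the definitions: substring
enumeration for G-runs, iterative arg-max for overlap resolution, recursive
path walking for NG86 differences, and exhaustive outcome enumeration for
the binomial test.  They share no code with the package internals.
"""

from __future__ import annotations

from itertools import product
from math import comb

from g4telo.pqs_scan import ScanParams


def oracle_run_spans(seq: str, params: ScanParams):
    """All legal (start, end, defective, longest_stretch) run spans, by
    exhaustive substring inspection."""
    spans = []
    n = len(seq)
    max_span = params.max_run + 1  # one optional 1-bp bulge
    for s in range(n):
        for e in range(s + params.min_run, min(n, s + max_span) + 1):
            sub = seq[s:e]
            if sub[0] != "G" or sub[-1] != "G":
                continue
            non_g = [c for c in sub if c != "G"]
            n_g = len(sub) - len(non_g)
            if not (params.min_run <= n_g <= params.max_run):
                continue
            if len(non_g) == 0:
                defective = False
            elif len(non_g) == 1 and non_g[0] != "N":
                defective = True
            else:
                continue
            stretch = max(len(p) for p in "".join(
                c if c == "G" else " " for c in sub
            ).split())
            spans.append((s, e, defective, stretch))
    return spans


def oracle_enumerate(seq: str, params: ScanParams):
    """All admissible 4-run placements with their scores.

    Returns a set of tuples (start, end, score, run_spans) for direct
    comparison with the scanner's candidate list.
    """
    seq = seq.upper()
    spans = oracle_run_spans(seq, params)
    by_start: dict[int, list] = {}
    for sp in spans:
        by_start.setdefault(sp[0], []).append(sp)

    out = set()
    for sp1 in spans:
        # chains built breadth-first over explicit loop-length choices
        chains = [[sp1]]
        for _ in range(3):
            nxt = []
            for chain in chains:
                last_end = chain[-1][1]
                for loop_len in range(params.loop_min, params.loop_max + 1):
                    for sp in by_start.get(last_end + loop_len, ()):
                        if sp[1] - chain[0][0] <= params.max_len:
                            nxt.append(chain + [sp])
            chains = nxt
        for chain in chains:
            n_def = sum(1 for sp in chain if sp[2])
            if n_def > params.max_defective_runs:
                continue
            start, end = chain[0][0], chain[-1][1]
            if "N" in seq[start:end]:
                continue
            t = min(sp[3] for sp in chain)
            loops = [chain[i + 1][0] - chain[i][1] for i in range(3)]
            score = (
                params.tetrad_bonus * (t - 1)
                - params.loop_penalty * sum(max(0, l - params.loop_free) for l in loops)
                - params.defect_penalty * n_def
            )
            if score >= params.min_score:
                out.add((start, end, score, tuple((sp[0], sp[1]) for sp in chain)))
    return out


def oracle_greedy(candidates):
    """Iterative arg-max non-overlap selection on (start, end, score, motif).

    Ties: highest score, then leftmost start, then shortest, then smallest
    motif string.  Returns the kept candidates as a set.
    """
    remaining = list(candidates)
    kept = []
    while remaining:
        best = remaining[0]
        for c in remaining[1:]:
            if (-c[2], c[0], c[1] - c[0], c[3]) < (-best[2], best[0], best[1] - best[0], best[3]):
                best = c
        kept.append(best)
        remaining = [c for c in remaining if c[1] <= best[0] or c[0] >= best[1]]
    return set(kept)


_STOPS = {"TAA", "TAG", "TGA"}
_CODE = None


def _genetic_code():
    global _CODE
    if _CODE is None:
        from Bio.Seq import Seq

        _CODE = {
            a + b + c: str(Seq(a + b + c).translate())
            for a, b, c in product("ACGT", repeat=3)
        }
    return _CODE


def oracle_pathways(codon_i: str, codon_j: str):
    """(syn, nonsyn) differences averaged over stop-free pathways, derived
    by recursive path walking (independent of the permutation-based code)."""
    code = _genetic_code()
    results = []

    def walk(cur: str, syn: int, non: int):
        if cur == codon_j:
            results.append((syn, non))
            return
        for pos in range(3):
            if cur[pos] != codon_j[pos]:
                nxt = cur[:pos] + codon_j[pos] + cur[pos + 1 :]
                if nxt in _STOPS:
                    continue
                step_syn = code[cur] == code[nxt]
                walk(nxt, syn + step_syn, non + (not step_syn))

    walk(codon_i, 0, 0)
    k = sum(1 for p in range(3) if codon_i[p] != codon_j[p])
    if not results:
        return 0.0, float(k)
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def oracle_binomial_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial p under p=0.5 by summing the probabilities
    of all outcomes no more probable than the observed count."""
    pmf = [comb(n, i) / 2**n for i in range(n + 1)]
    observed = pmf[k]
    return sum(p for p in pmf if p <= observed + 1e-12)
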
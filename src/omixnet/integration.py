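"""Merging evidence into per-condition signatures and their intersection.

Within a condition, each dataset/assay contributes a gene -> direction map
(RNA differential expression or signed H3K27ac region annotation).  A gene
seen with both directions anywhere within the condition is excluded as
discordant; the survivors carry a single direction.  Across conditions,
common genes split into concordant (same direction, the genes of interest)
and discordant sets.
"""

from __future__ import annotations

from .containers import CommonSignature, SignatureSet


def merge_condition_signature(
    lists: list[tuple[str, str, dict[str, int]]],
    condition: str = "",
) -> SignatureSet:
    """Union per-dataset gene->direction maps; exclude direction conflicts.

    ``lists`` holds (dataset id, assay, gene -> +1/-1) triples.  A single
    input map is rejected if malformed (non-sign values); conflicts *across*
    maps move the gene to ``excluded_discordant``.
    """
    if not lists:
        raise ValueError("at least one evidence list required")
    provenance: dict[str, list[tuple[str, str, int]]] = {}
    seen: dict[str, set[int]] = {}
    for dataset, assay, mapping in lists:
        for gene, direction in mapping.items():
            if direction not in (-1, 1):
                raise ValueError(
                    f"malformed evidence from {dataset}/{assay}: "
                    f"direction {direction!r} for {gene}"
                )
            seen.setdefault(gene, set()).add(direction)
            provenance.setdefault(gene, []).append((dataset, assay, direction))
    discordant = {g for g, dirs in seen.items() if len(dirs) > 1}
    directions = {g: next(iter(dirs)) for g, dirs in seen.items() if len(dirs) == 1}
    provenance = {g: sorted(v) for g, v in provenance.items() if g in directions}
    return SignatureSet(condition, directions, provenance, discordant)


def intersect_conditions(a: SignatureSet, b: SignatureSet) -> CommonSignature:
    """Common genes across conditions, split by direction agreement."""
    if not a.directions or not b.directions:
        raise ValueError("both signatures must be non-empty")
    common = a.genes & b.genes
    concordant = {g: a.directions[g] for g in common if a.directions[g] == b.directions[g]}
    discordant = common - set(concordant)
    return CommonSignature(common, concordant, discordant)
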
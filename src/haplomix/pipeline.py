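"""End-to-end orchestration: painting to admixture event.

Convenience layer used by the examples, tests and CLI: estimates painting
parameters, paints a recipient group and its surrogate groups against a
common donor panel, builds group copying vectors (self-copy zeroed and
rescaled), and runs the coancestry-curve admixture characterisation.
"""

from __future__ import annotations

import numpy as np

from .painting import (
    PaintingParameters,
    PaintingResult,
    estimate_painting_parameters,
    paint_haploid,
    summarise_copying_vectors,
)
from .panel import HaplotypePanel
from .globetrotter import AdmixtureEvent, run_globetrotter

__all__ = [
    "paint_group",
    "surrogate_copying_vectors",
    "characterise_admixture",
]


def paint_group(
    recipients: HaplotypePanel,
    donors: HaplotypePanel,
    params: PaintingParameters,
    n_samples: int = 10,
    seed: int | None = None,
) -> list[PaintingResult]:
    """Paint every recipient haploid against the donor panel."""
    rng = np.random.default_rng(seed)
    return [
        paint_haploid(
            recipients.haps[h], donors, params=params, n_samples=n_samples,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for h in range(recipients.n_hap)
    ]


def surrogate_copying_vectors(
    donors: HaplotypePanel,
    params: PaintingParameters,
    subset_per_group: int = 10,
    seed: int | None = None,
) -> tuple[np.ndarray, list]:
    """Copying vector of each donor group, painted within the donor panel.

    Each surrogate haploid is painted against all donor haploids except
    its own individual's; chunk lengths are summed per donor group and
    averaged over the group's recipients.  The self-copy entry is then
    zeroed and the vector rescaled (the drift component would otherwise
    dominate).  Returns (vectors (G, G), groups).
    """
    groups = donors.group_list()
    rng = np.random.default_rng(seed)
    vectors = np.zeros((len(groups), len(groups)))
    for gi, g in enumerate(groups):
        members = donors.haploids_of_group(g)
        chosen = members[: min(subset_per_group, members.size)]
        results, kept_groups = [], []
        for h in chosen:
            mate = h ^ 1
            keep = np.array(
                [j for j in range(donors.n_hap) if j not in (h, mate)]
            )
            sub = donors.take_haploids(keep)
            results.append(
                paint_haploid(
                    donors.haps[h], sub, params=params, n_samples=0,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            kept_groups.append(donors.groups[keep])
        acc = np.zeros(len(groups))
        for res, kg in zip(results, kept_groups):
            v, _ = summarise_copying_vectors([res], kg, group_order=groups)
            acc += v
        v = acc / len(results)
        v[gi] = 0.0  # zero the self-copy (drift) entry
        vectors[gi] = v / v.sum()
    return vectors, groups


def characterise_admixture(
    recipients: HaplotypePanel,
    donors: HaplotypePanel,
    params: PaintingParameters | None = None,
    n_samples: int = 10,
    subset_per_group: int = 10,
    seed: int | None = None,
    **globetrotter_kwargs,
) -> tuple[AdmixtureEvent, dict]:
    """Full characterisation of one recipient group.

    Estimates painting parameters by EM on the donor panel when none are
    given, paints recipients and surrogates, and runs the
    coancestry-curve inference.  Returns the event plus intermediates
    (paintings, copying vectors, parameters).
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params, _ = estimate_painting_parameters(
            donors, n_em=10, subset_per_group=2,
            chromosomes=donors.chromosomes[:1],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    paintings = paint_group(
        recipients, donors, params, n_samples=n_samples,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    groups = donors.group_list()
    group_idx = {g: i for i, g in enumerate(groups)}
    donor_group_idx = np.array([group_idx[g] for g in donors.groups])
    recipient_vector, _ = summarise_copying_vectors(
        paintings, donors.groups, group_order=groups
    )
    surrogate_vecs, _ = surrogate_copying_vectors(
        donors, params, subset_per_group=subset_per_group,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    event = run_globetrotter(
        paintings=paintings,
        donor_group_idx=donor_group_idx,
        site_cm=donors.cm,
        groups=groups,
        recipient_vector=recipient_vector,
        surrogate_vectors=surrogate_vecs,
        seed=int(rng.integers(0, 2**31 - 1)),
        **globetrotter_kwargs,
    )
    return event, {
        "paintings": paintings,
        "params": params,
        "recipient_vector": recipient_vector,
        "surrogate_vectors": surrogate_vecs,
        "groups": groups,
    }
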
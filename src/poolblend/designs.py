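"""Ready-made experiment layouts.

``mouse_design`` is the canonical one-color layout with variable pool sizes
that also drives the simulation study: two selection lines of 30 animals,
ten animals per line measured individually, six pools of five per line each
measured in technical duplicate (44 arrays in total), with the individually
measured animals re-used as members of the first two pools of their line.

``rat_design`` and ``bee_like_design`` cover the other two structural
flavours: every individual re-used across nested pool sizes (1, 2, 3, 12)
on one-color arrays, and a two-color loop over pooled compositions.
"""

from __future__ import annotations

from .design import Individual, Measurement, PoolDesign, PoolSpec

__all__ = [
    "mouse_design",
    "rat_design",
    "bee_like_design",
    "two_group_singles_design",
    "small_pooled_design",
]


def mouse_design() -> PoolDesign:
    """Two-line, 60-animal, 44-array one-color design with pools of five.

    Per line: animals 1-10 are measured singly (10 arrays) and constitute
    pools 1-2 (five animals each); pools 3-6 use animals 11-30.  Every pool
    is blended once and measured twice.  Measurement order per line: the 10
    singles, then pools 1-6 in technical duplicate.
    """
    individuals = []
    pools = []
    measurements = []
    for line, trt in (("L1", "control"), ("L2", "selected")):
        ids = [f"{line}m{i:02d}" for i in range(1, 31)]
        individuals += [Individual(id=i, treatment=trt) for i in ids]
        # singleton pools for the individually measured animals
        for i in range(10):
            pools.append(PoolSpec(id=f"{line}s{i + 1:02d}", members=(ids[i],)))
        for p in range(6):
            pools.append(PoolSpec(
                id=f"{line}p{p + 1}", members=tuple(ids[5 * p:5 * p + 5])))
        a = 0
        for i in range(10):
            a += 1
            measurements.append(Measurement(array=f"{line}a{a:02d}",
                                            sample=f"{line}s{i + 1:02d}"))
        for p in range(6):
            for _ in range(2):
                a += 1
                measurements.append(Measurement(array=f"{line}a{a:02d}",
                                                sample=f"{line}p{p + 1}"))
    return PoolDesign(
        platform="one-color",
        individuals=tuple(individuals),
        pools=tuple(pools),
        measurements=tuple(measurements),
        treatment_levels=("control", "selected"),
    )


def rat_design() -> PoolDesign:
    """Two-group one-color design re-using 12 rats per group at pool sizes 1/2/3/12.

    Per group: 12 singleton samples, 6 pools of two, 4 pools of three and
    one pool of twelve (23 samples), measured on 28 arrays (five pools
    measured twice).  Which samples carried the technical replicates is not
    part of the published description; this synthetic stand-in replicates
    the first five blend pools once each.  Blend pools are ordered so the
    blending covariance ``G2`` carries the diagonal
    (2/9, 1/4, 2/9, 1/4, 2/9, 1/4, 1/4, 1/4, 2/9, 1/4, 11/144) per group.
    """
    individuals = []
    pools = []
    measurements = []
    for grp, trt in (("A", "control"), ("B", "treated")):
        ids = [f"{grp}r{i:02d}" for i in range(1, 13)]
        individuals += [Individual(id=i, treatment=trt) for i in ids]
        for i in range(12):
            pools.append(PoolSpec(id=f"{grp}s{i + 1:02d}", members=(ids[i],)))
        trios = [tuple(ids[3 * k:3 * k + 3]) for k in range(4)]
        duos = [tuple(ids[2 * k:2 * k + 2]) for k in range(6)]
        ordered = [
            ("t1", trios[0]), ("d1", duos[0]), ("t2", trios[1]), ("d2", duos[1]),
            ("t3", trios[2]), ("d3", duos[2]), ("d4", duos[3]), ("d5", duos[4]),
            ("t4", trios[3]), ("d6", duos[5]), ("w1", tuple(ids)),
        ]
        pool_ids = []
        for name, members in ordered:
            pid = f"{grp}{name}"
            pools.append(PoolSpec(id=pid, members=members))
            pool_ids.append(pid)
        a = 0
        for i in range(12):
            a += 1
            measurements.append(Measurement(array=f"{grp}a{a:02d}",
                                            sample=f"{grp}s{i + 1:02d}"))
        for pid in pool_ids:
            a += 1
            measurements.append(Measurement(array=f"{grp}a{a:02d}", sample=pid))
        for pid in pool_ids[:5]:  # technical replicates
            a += 1
            measurements.append(Measurement(array=f"{grp}a{a:02d}", sample=pid))
    return PoolDesign(
        platform="one-color",
        individuals=tuple(individuals),
        pools=tuple(pools),
        measurements=tuple(measurements),
        treatment_levels=("control", "treated"),
    )


def bee_like_design() -> PoolDesign:
    """Synthetic 22-array two-color loop design over pooled nerve tissues.

    A stand-in for a 14-bee behavioural experiment (7 hygienic, 7 control)
    with six sample compositions of sizes 1, 2 and 4 hybridized across
    three tissues (mushroom body, antennal lobe, antennae); the exact
    published array wiring is not reproduced, only its structure: 22
    two-color arrays, fixed effects for the overall mean (absorbing dye),
    the behaviour difference and two tissue differences.
    """
    hyg = [f"h{i}" for i in range(1, 8)]
    ctl = [f"c{i}" for i in range(1, 8)]
    individuals = (
        [Individual(id=i, treatment="hygienic") for i in hyg]
        + [Individual(id=i, treatment="control") for i in ctl]
    )
    comps = {
        "C1": (hyg[0],),
        "C2": tuple(hyg[1:3]),
        "C3": tuple(hyg[3:7]),
        "C4": (ctl[0],),
        "C5": tuple(ctl[1:3]),
        "C6": tuple(ctl[3:7]),
    }
    pools = []
    for tissue in ("MB", "AL", "ANT"):
        for cid, members in comps.items():
            pools.append(PoolSpec(id=f"{cid}.{tissue}", members=members,
                                  blend_event=f"{cid}.{tissue}"))
    # dye-balanced comparisons, mostly within tissue plus a few cross-tissue
    # bridges that make the tissue differences estimable; AL lacks the
    # single-sample arrays
    wiring = [
        ("C1.MB", "C4.MB"), ("C5.MB", "C2.MB"), ("C3.MB", "C6.MB"),
        ("C4.MB", "C2.MB"), ("C1.MB", "C6.MB"), ("C6.MB", "C2.MB"),
        ("C3.MB", "C4.MB"),
        ("C5.AL", "C2.AL"), ("C3.AL", "C6.AL"), ("C2.AL", "C6.AL"),
        ("C6.AL", "C5.AL"), ("C2.AL", "C3.AL"),
        ("C4.ANT", "C1.ANT"), ("C2.ANT", "C5.ANT"), ("C6.ANT", "C3.ANT"),
        ("C2.ANT", "C4.ANT"), ("C6.ANT", "C1.ANT"), ("C4.ANT", "C3.ANT"),
        ("C2.MB", "C2.AL"), ("C5.AL", "C5.ANT"),
        ("C3.MB", "C3.ANT"), ("C6.AL", "C6.MB"),
    ]
    measurements = []
    for a, (red, green) in enumerate(wiring, start=1):
        arr = f"b{a:02d}"
        for sample, channel in ((red, "red"), (green, "green")):
            tissue = sample.split(".")[1]
            measurements.append(Measurement(array=arr, sample=sample,
                                            channel=channel,
                                            covariates={"tissue": tissue}))
    return PoolDesign(
        platform="two-color",
        individuals=tuple(individuals),
        pools=tuple(pools),
        measurements=tuple(measurements),
        treatment_levels=("control", "hygienic"),
        factors={"tissue": ("MB", "AL", "ANT")},
    )


def two_group_singles_design(n_per_group: int = 4, replicates: int = 1) -> PoolDesign:
    """All-individual (gamma = 1) one-color design, optionally with technical reps."""
    individuals = []
    pools = []
    measurements = []
    for grp, trt in (("A", "control"), ("B", "treated")):
        for i in range(n_per_group):
            iid = f"{grp}{i + 1}"
            individuals.append(Individual(id=iid, treatment=trt))
            pools.append(PoolSpec(id=f"s{iid}", members=(iid,)))
            for r in range(replicates):
                measurements.append(
                    Measurement(array=f"a{iid}.{r + 1}", sample=f"s{iid}"))
    return PoolDesign(
        platform="one-color",
        individuals=tuple(individuals),
        pools=tuple(pools),
        measurements=tuple(measurements),
        treatment_levels=("control", "treated"),
    )


def small_pooled_design(n_singles: int = 2, n_pools: int = 2, pool_size: int = 2,
                        replicates: int = 2) -> PoolDesign:
    """Small two-group design mixing singles and replicated pools (for tests)."""
    individuals = []
    pools = []
    measurements = []
    for grp, trt in (("A", "control"), ("B", "treated")):
        nxt = 0

        def new_ids(k: int):
            nonlocal nxt
            out = [f"{grp}i{nxt + j + 1}" for j in range(k)]
            nxt += k
            return out

        for s in range(n_singles):
            (iid,) = new_ids(1)
            individuals.append(Individual(id=iid, treatment=trt))
            pools.append(PoolSpec(id=f"{grp}s{s + 1}", members=(iid,)))
            measurements.append(Measurement(array=f"{grp}as{s + 1}",
                                            sample=f"{grp}s{s + 1}"))
        for p in range(n_pools):
            ids = new_ids(pool_size)
            individuals += [Individual(id=i, treatment=trt) for i in ids]
            pools.append(PoolSpec(id=f"{grp}p{p + 1}", members=tuple(ids)))
            for r in range(replicates):
                measurements.append(Measurement(array=f"{grp}ap{p + 1}.{r + 1}",
                                                sample=f"{grp}p{p + 1}"))
    return PoolDesign(
        platform="one-color",
        individuals=tuple(individuals),
        pools=tuple(pools),
        measurements=tuple(measurements),
        treatment_levels=("control", "treated"),
    )
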
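"""Programmatic construction of the two shipped hepatocyte schemes.

The shipped scheme files under ``labeldyn/schemes/`` are generated from this
module (``python -m labeldyn._builder`` regenerates them); a test asserts the
data files and the builder agree.  Users normally go through
:func:`labeldyn.network.build_scheme`, which reads the data files.

Atom-map conventions (1-based carbons):

* hexose interconversions (hk, g6pase, pfk, fbpase, gs, gp) — identity C1..C6;
* aldolase — fbp C1-C3 -> dhap C1-C3, fbp C4-C6 -> g3p C1-C3;
* triose-phosphate isomerase — dhap C1,C2,C3 -> g3p C3,C2,C1;
* lower glycolysis / lactate exchange — identity on trioses, so
  [1,2-13C2]glucose yields [2,3-13C2]lactate (m2);
* pdh — pyr C1 -> CO2, C2 -> accoa C1 (carbonyl), C3 -> accoa C2 (methyl);
* pc — pyr C1-C3 -> oaa C1-C3, CO2 -> oaa C4;
* pepck — oaa C1-C3 -> pep, oaa C4 -> CO2;
* citrate synthase + aconitase/IDH lumped — akg C1<-oaa C4, C2<-oaa C3,
  C3<-oaa C2, C4<-accoa methyl, C5<-accoa carbonyl; oaa C1 -> CO2;
* akg -> mal (through symmetric succinate/fumarate) — akg C1 -> CO2, the rest
  enters malate in either orientation with probability 1/2 each;
* mal <-> oaa — identity with a 1/2-1/2 orientation scramble (fumarase);
* oxidative PPP lump — hexP C1 -> CO2, C2-C6 -> p5p C1-C5;
* transketolase — the donor ketose keeps C1,C2 on the enzyme; transaldolase
  keeps C1-C3.
"""

from __future__ import annotations

from pathlib import Path

from .network import AtomMap, NetworkScheme, Pool, Reaction

__all__ = ["make_scheme", "toy_chain_scheme"]


def _identity(sub: str, prod: str, n: int):
    return [((sub, i), (prod, i)) for i in range(1, n + 1)]


def _ma(*params: str) -> dict:
    return {"law": "mass_action", "params": list(params)}


def _enzyme(eid: str, component: str) -> dict:
    return {"law": "enzyme", "enzyme": eid, "component": component}


def _pools(variant: str) -> dict[str, Pool]:
    pools = [
        Pool("glc_med", 6, "medium", 20.0),
        Pool("lac_med", 3, "medium", 0.0),
        Pool("glu", 5, "medium", 5e-4),
        Pool("hexP", 6, "cytosol", 0.10),
        Pool("fbp", 6, "cytosol", 0.03),
        Pool("dhap", 3, "cytosol", 0.04),
        Pool("g3p", 3, "cytosol", 0.01),
        Pool("pep", 3, "cytosol", 0.02),
        Pool("pyr", 3, "cytosol", 0.05),
        Pool("glycogen", 6, "cytosol", 0.02),
        Pool("p5p", 5, "cytosol", 0.01),
        Pool("s7p", 7, "cytosol", 0.005),
        Pool("e4p", 4, "cytosol", 0.002),
        Pool("accoa", 2, "mito", 1e-4),
        Pool("oaa", 4, "mito", 2e-4),
        Pool("mal", 4, "mito", 3e-4),
        Pool("akg", 5, "mito", 2e-4),
        # bicarbonate buffer dominates; untracked = unlabeled carbon source
        Pool("co2", 1, "mito", 1.0, is_tracked=False),
    ]
    if variant == "B":
        pools.append(Pool("hexP_chan", 6, "channel", 0.02))
    return {p.id: p for p in pools}


def make_scheme(variant: str) -> NetworkScheme:
    if variant not in ("A", "B"):
        raise ValueError(f"variant must be 'A' or 'B', got {variant!r}")
    pools = _pools(variant)
    rxns: list[Reaction] = []

    def add(rid, subs, prods, amap, law, kind="net"):
        rxns.append(
            Reaction(rid, tuple(subs), tuple(prods), amap, law, kind)
        )

    # --- upper glycolysis / glycogen -------------------------------------
    add(
        "hk1",
        [("glc_med", "glc_med")],
        [("hexP", "hexP")],
        AtomMap.single(_identity("glc_med", "hexP", 6)),
        {"law": "michaelis_menten", "params": ["Vmax_hk1", "Km_hk1"]},
    )
    add(
        "g6pase1",
        [("hexP", "hexP")],
        [("glc_med", "glc_med")],
        AtomMap.single(_identity("hexP", "glc_med", 6)),
        _ma("k_g6pase1"),
    )
    add(
        "pfk1",
        [("hexP", "hexP")],
        [("fbp", "fbp")],
        AtomMap.single(_identity("hexP", "fbp", 6)),
        _ma("k_pfk1"),
    )
    add(
        "fbpase1",
        [("fbp", "fbp")],
        [("hexP", "hexP")],
        AtomMap.single(_identity("fbp", "hexP", 6)),
        _ma("k_fbpase1"),
    )
    gs_source = "hexP_chan" if variant == "B" else "hexP"
    add(
        "gs",
        [(gs_source, gs_source)],
        [("glycogen", "glycogen")],
        AtomMap.single(_identity(gs_source, "glycogen", 6)),
        _ma("k_gs"),
    )
    add(
        "gp",
        [("glycogen", "glycogen")],
        [("hexP", "hexP")],
        AtomMap.single(_identity("glycogen", "hexP", 6)),
        _ma("k_gp"),
    )
    if variant == "B":
        add(
            "hk2",
            [("glc_med", "glc_med")],
            [("hexP_chan", "hexP_chan")],
            AtomMap.single(_identity("glc_med", "hexP_chan", 6)),
            {"law": "michaelis_menten", "params": ["Vmax_hk2", "Km_hk2"]},
        )
        add(
            "g6pase2",
            [("hexP_chan", "hexP_chan")],
            [("glc_med", "glc_med")],
            AtomMap.single(_identity("hexP_chan", "glc_med", 6)),
            _ma("k_g6pase2"),
        )
        add(
            "pfk2",
            [("hexP_chan", "hexP_chan")],
            [("fbp", "fbp")],
            AtomMap.single(_identity("hexP_chan", "fbp", 6)),
            _ma("k_pfk2"),
        )
        add(
            "fbpase2",
            [("fbp", "fbp")],
            [("hexP_chan", "hexP_chan")],
            AtomMap.single(_identity("fbp", "hexP_chan", 6)),
            _ma("k_fbpase2"),
        )

    # --- aldolase (three-step exchange enzyme) ---------------------------
    add(
        "aldf",
        [("fbp", "fbp")],
        [("dhap", "dhap"), ("g3p", "g3p")],
        AtomMap.single(
            [((("fbp"), c), ("dhap", c)) for c in (1, 2, 3)]
            + [(("fbp", c), ("g3p", c - 3)) for c in (4, 5, 6)]
        ),
        _enzyme("ald", "vf"),
    )
    add(
        "aldr",
        [("dhap", "dhap"), ("g3p", "g3p")],
        [("fbp", "fbp")],
        AtomMap.single(
            [(("dhap", c), ("fbp", c)) for c in (1, 2, 3)]
            + [(("g3p", c), ("fbp", c + 3)) for c in (1, 2, 3)]
        ),
        _enzyme("ald", "vr"),
    )
    # half-molecule exchange: fbp C4-C6 swaps with the g3p pool
    add(
        "aldhx",
        [("fbp", "fbp"), ("g3p", "g3p")],
        [("fbp_o", "fbp"), ("g3p_o", "g3p")],
        AtomMap.single(
            [(("fbp", c), ("fbp_o", c)) for c in (1, 2, 3)]
            + [(("g3p", c), ("fbp_o", c + 3)) for c in (1, 2, 3)]
            + [(("fbp", c), ("g3p_o", c - 3)) for c in (4, 5, 6)]
        ),
        _enzyme("ald", "vhx"),
        kind="exchange",
    )
    # label-only triose isomerase exchange (swap a dhap with a g3p)
    add(
        "aldex",
        [("dhap", "dhap"), ("g3p", "g3p")],
        [("dhap_o", "dhap"), ("g3p_o", "g3p")],
        AtomMap.single(
            [(("dhap", c), ("g3p_o", 4 - c)) for c in (1, 2, 3)]
            + [(("g3p", c), ("dhap_o", 4 - c)) for c in (1, 2, 3)]
        ),
        _ma("k_aldex"),
        kind="exchange",
    )
    # net triose isomerase (carries the mass flow dhap <-> g3p)
    add(
        "tpif",
        [("dhap", "dhap")],
        [("g3p", "g3p")],
        AtomMap.single([(("dhap", c), ("g3p", 4 - c)) for c in (1, 2, 3)]),
        _ma("k_tpif"),
    )
    add(
        "tpir",
        [("g3p", "g3p")],
        [("dhap", "dhap")],
        AtomMap.single([(("g3p", c), ("dhap", 4 - c)) for c in (1, 2, 3)]),
        _ma("k_tpir"),
    )

    # --- lower glycolysis / lactate --------------------------------------
    add(
        "g3pep",
        [("g3p", "g3p")],
        [("pep", "pep")],
        AtomMap.single(_identity("g3p", "pep", 3)),
        _ma("k_g3pep"),
    )
    add(
        "pepg3",
        [("pep", "pep")],
        [("g3p", "g3p")],
        AtomMap.single(_identity("pep", "g3p", 3)),
        _ma("k_pepg3"),
    )
    add(
        "pk",
        [("pep", "pep")],
        [("pyr", "pyr")],
        AtomMap.single(_identity("pep", "pyr", 3)),
        _ma("k_pk"),
    )
    add(
        "lacin",
        [("lac_med", "lac_med")],
        [("pyr", "pyr")],
        AtomMap.single(_identity("lac_med", "pyr", 3)),
        _ma("k_lacin"),
    )
    add(
        "lacout",
        [("pyr", "pyr")],
        [("lac_med", "lac_med")],
        AtomMap.single(_identity("pyr", "lac_med", 3)),
        _ma("k_lacout"),
    )

    # --- anaplerosis / TCA lumps -----------------------------------------
    add(
        "pdh",
        [("pyr", "pyr")],
        [("accoa", "accoa")],
        AtomMap.single(
            [(("pyr", 2), ("accoa", 1)), (("pyr", 3), ("accoa", 2))],
            released=[("pyr", 1)],
        ),
        _ma("k_pdh"),
    )
    add(
        "pc",
        [("pyr", "pyr"), ("co2", "co2")],
        [("oaa", "oaa")],
        AtomMap.single(
            [(("pyr", c), ("oaa", c)) for c in (1, 2, 3)] + [(("co2", 1), ("oaa", 4))]
        ),
        _ma("k_pc"),
    )
    add(
        "pepck",
        [("oaa", "oaa")],
        [("pep", "pep")],
        AtomMap.single(
            [(("oaa", c), ("pep", c)) for c in (1, 2, 3)], released=[("oaa", 4)]
        ),
        _ma("k_pepck"),
    )
    add(
        "cs",
        [("oaa", "oaa"), ("accoa", "accoa")],
        [("akg", "akg")],
        AtomMap.single(
            [
                (("oaa", 4), ("akg", 1)),
                (("oaa", 3), ("akg", 2)),
                (("oaa", 2), ("akg", 3)),
                (("accoa", 2), ("akg", 4)),
                (("accoa", 1), ("akg", 5)),
            ],
            released=[("oaa", 1)],
        ),
        _ma("k_cs"),
    )
    add(
        "citmal",
        [("akg", "akg")],
        [("mal", "mal")],
        AtomMap.scrambled(
            [
                (
                    0.5,
                    [(("akg", c), ("mal", c - 1)) for c in (2, 3, 4, 5)],
                    [("akg", 1)],
                ),
                (
                    0.5,
                    [(("akg", c), ("mal", 6 - c)) for c in (2, 3, 4, 5)],
                    [("akg", 1)],
                ),
            ]
        ),
        _ma("k_citmal"),
    )
    _fum = AtomMap.scrambled(
        [
            (0.5, [(("s", c), ("p", c)) for c in (1, 2, 3, 4)], []),
            (0.5, [(("s", c), ("p", 5 - c)) for c in (1, 2, 3, 4)], []),
        ]
    )
    add("maloa", [("s", "mal")], [("p", "oaa")], _fum, _ma("k_maloa"))
    add("oamal", [("s", "oaa")], [("p", "mal")], _fum, _ma("k_oamal"))
    # glutamate equilibrates with akg without net flux
    add(
        "akgglu",
        [("akg", "akg"), ("glu", "glu")],
        [("akg_o", "akg"), ("glu_o", "glu")],
        AtomMap.single(
            [(("akg", c), ("glu_o", c)) for c in range(1, 6)]
            + [(("glu", c), ("akg_o", c)) for c in range(1, 6)]
        ),
        _ma("k_akgglu"),
        kind="exchange",
    )

    # --- pentose phosphate pathway ---------------------------------------
    add(
        "g6pdh",
        [("hexP", "hexP")],
        [("p5p", "p5p")],
        AtomMap.single(
            [(("hexP", c), ("p5p", c - 1)) for c in range(2, 7)],
            released=[("hexP", 1)],
        ),
        _ma("k_g6pdh"),
    )
    # transketolase 1: p5p(donor) + p5p(acceptor) <-> s7p + g3p
    add(
        "p5p>s7p",
        [("don", "p5p"), ("acc", "p5p")],
        [("s7p", "s7p"), ("g3p", "g3p")],
        AtomMap.single(
            [(("don", 1), ("s7p", 1)), (("don", 2), ("s7p", 2))]
            + [(("acc", c), ("s7p", c + 2)) for c in range(1, 6)]
            + [(("don", c), ("g3p", c - 2)) for c in (3, 4, 5)]
        ),
        _enzyme("tk1", "vf"),
    )
    add(
        "s7p>r5p",
        [("s7p", "s7p"), ("g3p", "g3p")],
        [("don", "p5p"), ("acc", "p5p")],
        AtomMap.single(
            [(("s7p", 1), ("don", 1)), (("s7p", 2), ("don", 2))]
            + [(("g3p", c), ("don", c + 2)) for c in (1, 2, 3)]
            + [(("s7p", c), ("acc", c - 2)) for c in range(3, 8)]
        ),
        _enzyme("tk1", "vr"),
    )
    # transketolase donor-half exchange: p5p C3-C5 <-> g3p pool
    add(
        "p5p-g3p",
        [("p5p", "p5p"), ("g3p", "g3p")],
        [("p5p_o", "p5p"), ("g3p_o", "g3p")],
        AtomMap.single(
            [(("p5p", 1), ("p5p_o", 1)), (("p5p", 2), ("p5p_o", 2))]
            + [(("g3p", c), ("p5p_o", c + 2)) for c in (1, 2, 3)]
            + [(("p5p", c), ("g3p_o", c - 2)) for c in (3, 4, 5)]
        ),
        _enzyme("tk1", "vhx"),
        kind="exchange",
    )
    # transketolase 2: p5p(donor) + e4p <-> f6p(hexP) + g3p
    add(
        "p5p>f6p",
        [("don", "p5p"), ("e4p", "e4p")],
        [("hexP", "hexP"), ("g3p", "g3p")],
        AtomMap.single(
            [(("don", 1), ("hexP", 1)), (("don", 2), ("hexP", 2))]
            + [(("e4p", c), ("hexP", c + 2)) for c in (1, 2, 3, 4)]
            + [(("don", c), ("g3p", c - 2)) for c in (3, 4, 5)]
        ),
        _enzyme("tk2", "vf"),
    )
    add(
        "f6p>p5p",
        [("hexP", "hexP"), ("g3p", "g3p")],
        [("don", "p5p"), ("e4p", "e4p")],
        AtomMap.single(
            [(("hexP", 1), ("don", 1)), (("hexP", 2), ("don", 2))]
            + [(("g3p", c), ("don", c + 2)) for c in (1, 2, 3)]
            + [(("hexP", c), ("e4p", c - 2)) for c in (3, 4, 5, 6)]
        ),
        _enzyme("tk2", "vr"),
    )
    # transaldolase: s7p + g3p <-> f6p(hexP) + e4p
    add(
        "s7p>f6p",
        [("s7p", "s7p"), ("g3p", "g3p")],
        [("hexP", "hexP"), ("e4p", "e4p")],
        AtomMap.single(
            [(("s7p", c), ("hexP", c)) for c in (1, 2, 3)]
            + [(("g3p", c), ("hexP", c + 3)) for c in (1, 2, 3)]
            + [(("s7p", c), ("e4p", c - 3)) for c in (4, 5, 6, 7)]
        ),
        _enzyme("ta", "vf"),
    )
    add(
        "f6p>s7p",
        [("hexP", "hexP"), ("e4p", "e4p")],
        [("s7p", "s7p"), ("g3p", "g3p")],
        AtomMap.single(
            [(("hexP", c), ("s7p", c)) for c in (1, 2, 3)]
            + [(("e4p", c), ("s7p", c + 3)) for c in (1, 2, 3, 4)]
            + [(("hexP", c), ("g3p", c - 3)) for c in (4, 5, 6)]
        ),
        _enzyme("ta", "vr"),
    )
    # transaldolase acceptor-half exchange: s7p C4-C7 <-> e4p pool
    add(
        "s7p-e4p",
        [("s7p", "s7p"), ("e4p", "e4p")],
        [("s7p_o", "s7p"), ("e4p_o", "e4p")],
        AtomMap.single(
            [(("s7p", c), ("s7p_o", c)) for c in (1, 2, 3)]
            + [(("e4p", c), ("s7p_o", c + 3)) for c in (1, 2, 3, 4)]
            + [(("s7p", c), ("e4p_o", c - 3)) for c in (4, 5, 6, 7)]
        ),
        _enzyme("ta", "vhx"),
        kind="exchange",
    )
    # standalone half-molecule exchanges (own rate constants)
    add(
        "f6p-g3p",
        [("hexP", "hexP"), ("g3p", "g3p")],
        [("hexP_o", "hexP"), ("g3p_o", "g3p")],
        AtomMap.single(
            [(("hexP", c), ("hexP_o", c)) for c in (1, 2, 3)]
            + [(("g3p", c), ("hexP_o", c + 3)) for c in (1, 2, 3)]
            + [(("hexP", c), ("g3p_o", c - 3)) for c in (4, 5, 6)]
        ),
        _ma("k_f6pg3p"),
        kind="exchange",
    )
    add(
        "f6p-s7p",
        [("hexP", "hexP"), ("s7p", "s7p")],
        [("hexP_o", "hexP"), ("s7p_o", "s7p")],
        AtomMap.single(
            [(("hexP", c), ("s7p_o", c)) for c in (1, 2, 3)]
            + [(("s7p", c), ("hexP_o", c)) for c in (1, 2, 3)]
            + [(("hexP", c), ("hexP_o", c)) for c in (4, 5, 6)]
            + [(("s7p", c), ("s7p_o", c)) for c in (4, 5, 6, 7)]
        ),
        _ma("k_f6ps7p"),
        kind="exchange",
    )
    add(
        "p5p-s7p",
        [("p5p", "p5p"), ("s7p", "s7p")],
        [("p5p_o", "p5p"), ("s7p_o", "s7p")],
        AtomMap.single(
            [(("s7p", 1), ("s7p_o", 1)), (("s7p", 2), ("s7p_o", 2))]
            + [(("p5p", c), ("s7p_o", c + 2)) for c in range(1, 6)]
            + [(("s7p", c), ("p5p_o", c - 2)) for c in range(3, 8)]
        ),
        _ma("k_p5ps7p"),
        kind="exchange",
    )

    enzymes = {
        "ald": {
            "v1": ("ald_k1", "fbp"),
            "v2": ("ald_k2", None),
            "v3": ("ald_k3", None),
            "vm1": ("ald_km1", None),
            "vm2": ("ald_km2", "g3p"),
            "vm3": ("ald_km3", "dhap"),
        },
        "tk1": {
            "v1": ("tk1_k1", "p5p"),
            "v2": ("tk1_k2", None),
            "v3": ("tk1_k3", "p5p"),
            "vm1": ("tk1_km1", None),
            "vm2": ("tk1_km2", "g3p"),
            "vm3": ("tk1_km3", "s7p"),
        },
        "tk2": {
            "v1": ("tk2_k1", "p5p"),
            "v2": ("tk2_k2", None),
            "v3": ("tk2_k3", "e4p"),
            "vm1": ("tk2_km1", None),
            "vm2": ("tk2_km2", "g3p"),
            "vm3": ("tk2_km3", "hexP"),
        },
        "ta": {
            "v1": ("ta_k1", "s7p"),
            "v2": ("ta_k2", None),
            "v3": ("ta_k3", "g3p"),
            "vm1": ("ta_km1", None),
            "vm2": ("ta_km2", "e4p"),
            "vm3": ("ta_km3", "hexP"),
        },
    }

    return NetworkScheme(
        variant=variant,
        pools=pools,
        reactions={r.id: r for r in rxns},
        enzymes=enzymes,
        fast_equilibrium_groups={
            "hexP": ["g6p", "f6p"],
            "p5p": ["r5p", "xu5p", "ru5p"],
        },
    )


def toy_chain_scheme(n_pools: int = 3, k: float = 1.0) -> NetworkScheme:
    """A small linear chain of 2-carbon pools, X1 -> X2 -> ... (mass action).

    Used throughout the tests as a tractable system with closed-form behavior.
    """
    pools = {
        f"X{i}": Pool(f"X{i}", 2, "cytosol", 1.0 if i == 1 else 0.5)
        for i in range(1, n_pools + 1)
    }
    rxns = {}
    for i in range(1, n_pools):
        rid = f"r{i}"
        rxns[rid] = Reaction(
            rid,
            ((f"X{i}", f"X{i}"),),
            ((f"X{i+1}", f"X{i+1}"),),
            AtomMap.single([((f"X{i}", c), (f"X{i+1}", c)) for c in (1, 2)]),
            {"law": "mass_action", "params": [f"k_{rid}"]},
        )
    return NetworkScheme("toy", pools, rxns)


def main() -> None:
    out_dir = Path(__file__).parent / "schemes"
    out_dir.mkdir(exist_ok=True)
    from .network import save_scheme, validate_atom_maps

    for variant in ("A", "B"):
        scheme = make_scheme(variant)
        violations = validate_atom_maps(scheme)
        if violations:
            raise SystemExit("\n".join(violations))
        save_scheme(scheme, out_dir / f"scheme_{variant}.json")
        print(f"wrote scheme_{variant}.json "
              f"({len(scheme.pools)} pools, {len(scheme.reactions)} reactions)")


if __name__ == "__main__":
    main()
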
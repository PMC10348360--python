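"""Generate the packaged surrogate tables:

- src/smgbert/data/nmr_environments.csv : radius-1 environment -> shift (ppm)
- src/smgbert/data/bde_table.csv        : (elem_i, elem_j, order) -> BDE (kJ/mol)

NMR values come from a base+increment closed form; the environment space is the
exhaustive set of valence-consistent radius-1 environments over the fixture
generator's element/bond space, plus aromatic-carbon/nitrogen environments.
"""

import itertools
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "smgbert" / "data"

# ---- NMR surrogate -----------------------------------------------------------
# Each element owns a disjoint shift band (mimicking how different nuclei live
# on entirely different shift scales); the environment modulates the position
# inside the band.  Values are surrogates, not physical predictions.
BAND = {  # element -> (band_lo, band_width) in ppm
    "C": (0.0, 120.0), "N": (130.0, 50.0), "O": (190.0, 50.0), "S": (250.0, 40.0),
    "F": (-50.0, 14.0), "Cl": (-34.0, 14.0), "Br": (-18.0, 14.0),
    "I": (240.0, 9.0), "P": (291.0, 8.0),
}
# raw increment per neighbor descriptor (order char + element)
INC = {
    "-C": 9.0, "-N": 22.0, "-O": 42.0, "-S": 12.0, "-F": 68.0, "-Cl": 32.0,
    "-Br": 22.0, "-I": 12.0, "-P": 10.0,
    "=O": 150.0, "=C": 95.0, "=N": 110.0, "=S": 90.0,
    "#C": 62.0, "#N": 98.0,
    ":C": 55.0, ":N": 62.0,
}
VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}
ORDER_COST = {"-": 1, "=": 2, "#": 3, ":": 1.5}

SINGLES = ["-C", "-N", "-O", "-S", "-F", "-Cl", "-Br"]


def shift(center, neighbors):
    lo, width = BAND[center]
    raw = sum(INC[d] for d in neighbors)
    return lo + (raw % width)


def enumerate_envs():
    envs = {}

    def add(center, descs):
        key = f"{center}|{';'.join(sorted(descs))}"
        envs[key] = shift(center, descs)

    # acyclic tree space: single bonds among SINGLES plus at most one =O
    for center, val in VALENCE.items():
        for k in range(1, val + 1):
            for combo in itertools.combinations_with_replacement(SINGLES, k):
                if k <= val:
                    add(center, list(combo))
                # same combo with one neighbor swapped for =O (costs 2)
                if center in ("C", "N", "S") and k - 1 + 2 <= val:
                    add(center, list(combo[: k - 1]) + ["=O"])
        if center in ("C", "N", "S") and val >= 2:
            add(center, ["=O"])
    # the oxygen-side view of X=O double bonds (and O=O)
    for d in ("=C", "=N", "=S", "=O"):
        add("O", [d])
    # triple bonds from the C#N benzene substituent
    add("C", ["#N", "-C"])
    add("N", ["#C"])
    add("C", ["#C"])
    add("C", ["#C", "-C"])
    # aromatic carbons: ring CH, ring with one substituent
    add("C", [":C", ":C"])
    for d in SINGLES + ["-C", "=O"]:
        if ORDER_COST[d[0]] + 3 <= 4:
            add("C", [":C", ":C", d])
    # aromatic N (pyridine-like), in case users feed such rings
    add("N", [":C", ":C"])
    return envs


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    envs = enumerate_envs()
    with open(OUT / "nmr_environments.csv", "w") as fh:
        fh.write("env_key,shift_ppm,note\n")
        for key in sorted(envs):
            fh.write(f"{key},{envs[key]:.1f},surrogate closed form\n")
    print("nmr rows:", len(envs))

    # ---- BDE table: literature-typical mean values, kJ/mol -------------------
    bde = {
        ("C", "C", "single"): 347.0, ("C", "C", "double"): 614.0,
        ("C", "C", "triple"): 839.0, ("C", "C", "aromatic"): 518.0,
        ("C", "N", "single"): 305.0, ("C", "N", "double"): 615.0,
        ("C", "N", "triple"): 891.0, ("C", "N", "aromatic"): 508.0,
        ("C", "O", "single"): 358.0, ("C", "O", "double"): 745.0,
        ("C", "F", "single"): 485.0, ("C", "Cl", "single"): 327.0,
        ("C", "Br", "single"): 285.0, ("C", "I", "single"): 213.0,
        ("C", "S", "single"): 259.0, ("C", "S", "double"): 573.0,
        ("N", "N", "single"): 163.0, ("N", "N", "double"): 418.0,
        ("N", "O", "single"): 201.0, ("N", "O", "double"): 607.0,
        ("O", "O", "single"): 146.0, ("O", "S", "single"): 265.0,
        ("O", "S", "double"): 522.0, ("S", "S", "single"): 266.0,
        ("N", "S", "single"): 247.0, ("O", "P", "single"): 335.0,
        ("O", "P", "double"): 544.0, ("C", "P", "single"): 264.0,
        # halogen-heteroatom single bonds (fixture trees attach halogens to
        # any free-valence parent)
        ("N", "F", "single"): 272.0, ("N", "Cl", "single"): 200.0,
        ("N", "Br", "single"): 243.0, ("O", "F", "single"): 190.0,
        ("O", "Cl", "single"): 203.0, ("O", "Br", "single"): 235.0,
        ("S", "F", "single"): 284.0, ("S", "Cl", "single"): 255.0,
        ("S", "Br", "single"): 218.0,
    }
    with open(OUT / "bde_table.csv", "w") as fh:
        fh.write("elem_a,elem_b,order,bde_kj_mol,note\n")
        for (a, b, o), v in sorted(bde.items()):
            x, y = sorted((a, b))   # lookup key order is alphabetical
            fh.write(f"{x},{y},{o},{v:.1f},literature-typical mean\n")
    print("bde rows:", len(bde))


if __name__ == "__main__":
    main()
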
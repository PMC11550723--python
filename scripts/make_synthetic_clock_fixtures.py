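"""Regenerate the synthetic clock coefficient fixtures.

The seven bundled CSVs mirror the published clocks' site counts (Horvath
353, Hannum 71, Weidner 102, Zhang elastic-net 514; PhenoAge 513, DNAmTL
140, DunedinPACE 173) and the within-generation sharing that yields 967
unique first-generation and 821 unique second/third-generation sites, plus
a small cross-generation overlap.  CpG identifiers and coefficient values
are synthetic stand-ins, not the published coefficients.

Run from the repository root:  python scripts/make_synthetic_clock_fixtures.py
"""

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "clocktraj" / "data" / "synthetic_clocks"

rng = np.random.default_rng(20240450)
_counter = 0


def new_ids(n: int) -> list[str]:
    global _counter
    ids = [f"cg{_counter + i:08d}" for i in range(n)]
    _counter += n
    return ids


def coefs(n: int, sign: int | None = None) -> np.ndarray:
    c = rng.normal(0.0, 0.3, n)
    c[c == 0] = 0.1
    if sign is not None:
        c = sign * np.abs(c)
    return np.round(c, 6)


def write(stem: str, ids: list[str], cs: np.ndarray) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lines = ["cpg_id,coefficient"] + [f"{i},{c}" for i, c in zip(ids, cs)]
    (OUT / f"{stem}.csv").write_text("\n".join(lines) + "\n")


def main() -> None:
    horvath = new_ids(353)
    hannum = new_ids(71)
    weidner = new_ids(102)
    # Zhang shares 73 sites with Horvath -> first-gen union 353+71+102+441 = 967
    zhang = horvath[:73] + new_ids(441)
    # PhenoAge shares 10 sites with Horvath (cross-generation overlap)
    phenoage = horvath[100:110] + new_ids(503)
    # DNAmTL shares 5 sites with PhenoAge -> second/third union 513+135+173 = 821
    dnamtl = phenoage[200:205] + new_ids(135)
    dunedin = new_ids(173)

    write("horvath_synthetic", horvath, coefs(353))
    write("hannum_synthetic", hannum, coefs(71))
    write("weidner_synthetic", weidner, coefs(102))
    write("zhang_en_synthetic", zhang, coefs(514))
    write("phenoage_synthetic", phenoage, coefs(513))
    # telomere-length clock: stored with negative-leaning coefficients
    write("dnamtl_synthetic", dnamtl, coefs(140, sign=-1))
    write("dunedinpace_synthetic", dunedin, coefs(173))
    print(f"wrote 7 fixtures under {OUT}")


if __name__ == "__main__":
    main()
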
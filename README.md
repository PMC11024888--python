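# gslprof

Automated structural annotation and quantitation of **intact
glycosphingolipids** (GSLs) from positive-mode nanoLC-ESI-MS/MS runs —
sphingomyelins, cerebrosides, sulfatides and the ganglio-series
gangliosides profiled from tissue, serum or cultured cells. It is aimed
at lipidomics/glycomics practitioners who have centroided mzML data and
want rule-based, reproducible identifications instead of manual spectrum
reading or closed vendor software.

## What it does

Intact sphingolipids are ceramides (a long-chain base, LCB, amide-linked
to an N-acyl chain) carrying a polar headgroup. `gslprof` exploits the
tight biosynthetic constraints of the human sphingolipidome to keep the
search space small and the evidence rules sharp:

1. **Structure database** — all ceramides with 32–44 total carbons, 2–3
   free hydroxyls and ≤ 3 double bonds over the five human LCBs (d18:0,
   d18:1, d18:2, t18:0, t18:1), crossed with an editable headgroup
   catalog (SM, 1P, Hex, Lac, Gb3, GA1, sulfatides, GM/GD/GT/GQ
   gangliosides, Fuc- variants). Monoisotopic masses throughout.
2. **Adduct/charge enumeration** — [M+H]⁺, [M+NH₄]⁺, [M+2H]²⁺,
   [M+H+NH₄]²⁺, [M+2NH₄]²⁺ with headgroup-dependent charge preference;
   adduct areas are summed into compound abundances.
3. **CID fragment prediction** — glycan B-type oxocarbenium ions
   (m/z = Σ residue masses + proton; Hex 162.0528, HexNAc 203.0794,
   Fuc 146.0579, Neu5Ac 291.0954), telescoping Y-type neutral losses,
   ceramide/LCB water-loss ions, and headgroup diagnostics
   (phosphocholine 184.1; sulfatide −H₂O−SO₃).
4. **Scoring** — a 0–20 composite (fragments 0–10, precursor mass error
   0–5 at 25 ppm, relative retention time 0–5), accepted at ≥ 10.
5. **Retention modeling** — headgroup RRT table anchored on
   sphingomyelin (Hex 0.987 … GQ1 0.700), linear acyl-chain retention
   fits to rescue precursor-only homologs, and LCB elution-order checks.
6. **False-positive control** — PC/PE phospholipid vetoes (184.1
   fragment with even nominal precursor; neutral loss of 141), and
   removal of in-source artifacts (sulfatide → HexCer mass, GD3 → GM3)
   that co-elute with their parent at ≤ 1 % of its area.
7. **Sialidase differencing** — α2-3,6,8-neuraminidase cleaves terminal
   sialic acids but spares those on the first core galactose, so an
   untreated/treated pair pins down a/b/c-series (GD1a vs GD1b, …) via a
   joint per-ceramide fit.
8. **Aggregation & QC** — per-sample compound lists merged into a
   structures × samples matrix, percent relative abundances, ≥ 0.01 %
   heatmap filter, and replicate %RSD over compounds > 0.1 %.

A synthetic-run generator (`gslprof.synth`) produces ground-truthed mzML
runs — RRT-governed Gaussian elution, class-typical adducts,
rule-generated CID spectra, noise, in-source artifacts, treated
counterparts — so the entire pipeline is testable without instrument
data.

## Worked example

```sh
$ gslprof simulate --out-dir sim --seed 7      # ground-truthed benchmark run
wrote sim/run.mzML
$ gslprof annotate sim/run.mzML --out sample1.csv
40 accepted identifications -> sample1.csv
$ head -4 sample1.csv
name,formula,mass,rt,rrt,adducts,total_abundance,score,flags
GQ1-d18:1/C18,C106H182N6O55,2419.1629,31.550,0.7011,[M+2H]2+;[M+2NH4]2+;[M+H+NH4]2+,583819.33,19.42,
GQ1-d18:1/C20,C108H186N6O55,2447.1942,31.550,0.6988,[M+2H]2+;[M+2NH4]2+;[M+H+NH4]2+,349834.81,18.96,
GT1-d18:0/C18,C95H167N5O47,2130.0831,32.550,0.7233,[M+2H]2+;[M+2NH4]2+;[M+H+NH4]2+,235472.52,19.68,
```

All 40 injected structures are recovered: each line shows the observed
RRT sitting on its headgroup's expected value (GQ1 ≈ 0.700, GT1 ≈
0.724), the summed adduct abundance, and a library score close to the
20-point maximum (full CID match, sub-ppm precursor, RRT on target).
Replicate QC over simulated injections:

```sh
$ gslprof simulate-replicates --n 4 --cv 0.115 --seed 7 --out-dir reps
$ gslprof qc reps/*.csv --out qc.csv
mean %RSD over 40 compounds: 9.20
```

In the library:

```python
>>> from gslprof.fragments import glycan_b_ion
>>> from gslprof.chem import round_half_up
>>> round_half_up(glycan_b_ion({"Hex": 1, "HexNAc": 1, "Neu5Ac": 1}))
657.2
```

— the B-ion of the monosialylated trisaccharide seen in ganglioside
MS/MS spectra.

Other commands: `build-db`, `predict-fragments` (in-silico spectral
library CSV), `sialidase-diff` (series assignment from an
untreated/treated pair), `aggregate` (matrix + heatmap). Global
`--config` takes a YAML file overriding the defaults (25/50 ppm
tolerances, score ≥ 10, RRT tolerance ±0.015, 1 % artifact ceiling).

## Layout

```
src/gslprof/
  chem.py        elemental compositions, masses, adducts, ppm logic
  structures.py  LCB/acyl/headgroup types, enumeration, database CSV
  fragments.py   CID fragment rules and contaminant discriminators
  rt.py          RRT table, acyl-chain regression, elution-order rules
  features.py    EICs, peak detection, adduct grouping
  mzml_io.py     minimal mzML writer/reader (centroided, 64-bit)
  annotate.py    scoring, isobar/in-source resolution, compound lists
  sialidase.py   digest rule and a/b/c-series assignment
  synth.py       ground-truthed synthetic runs and replicates
  aggregate.py   matrix merge, relative abundance, heatmap, %RSD
  cli.py         the `gslprof` command-line interface
```
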
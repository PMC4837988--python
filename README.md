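# ltafrag

In-silico fragmentation, tandem-MS annotation and precursor-ion-scan
emulation for lipoteichoic-acid (LTA) glycolipids and the other polar lipids
that dominate direct-infusion spectra of *Bacillus subtilis* membrane
extracts.

## The scientific problem

Gram-positive bacteria anchor lipoteichoic acid — a poly(glycerophosphate)
polymer — to the membrane through a diglucosyl-diacylglycerol glycolipid
(DAG-Glc-Glc). The nascent polymer starts as an *LTA primer* carrying a
single phosphoglycerol unit (DAG-Glc-Glc-P-Gro), and the DltABCD machinery
esterifies the glycerol hydroxyls with D-alanine, partially neutralising the
cell surface. Identifying the anchor, the primer and its mono- and
di-alanylated derivatives in a crude lipid extract rests on three pieces of
mass arithmetic:

* **Molecular ions.** Neutral glycolipids sodiate in positive mode
  (`[M+Na]+`, Na atom mass added); phosphate-bearing lipids deprotonate
  (`[M−H]−`, proton mass subtracted); cardiolipin appears as its `[M−2H]2−`
  dianion. E.g. the (32:0) anchor computes to m/z 915.602 sodiated, and the
  (30:0) primer / mono-Ala / di-Ala series to 1017.577 / 1088.614 / 1159.651
  deprotonated — spaced by 71.037, the residue mass of an ester-linked
  (dehydrated) alanine.
* **Fragments.** Cutting 1–3 labelled scissile bonds of the residue graph,
  with each cut either retaining or losing the bond's water (and, in positive
  mode, optionally a hydroxyl), regenerates the full published fragment
  tables — the `− H`, `− H3O`, `− H5O2` anion families, fatty-acid vs ketene
  losses, and the sodiated / hydroxide-loss cation series.
* **Diagnostic precursor scans.** Three fragment channels pick each lipid
  family out of a mixture: 347.095 (sodiated dehydrated diglucose → anchors),
  152.996 (cyclic glycerophosphate anion → terminal-phosphoglycerol lipids),
  and 88.040 (deprotonated alanine → alanylated lipids).

The package implements all three stages plus a seeded synthetic-spectrum
generator emulating the direct-infusion data, so the whole pipeline is
testable without instrument files.

## Worked example

```python
>>> import ltafrag as lf
>>> primer = lf.parse_species("(30:0) DAG-Glc-Glc-P-Gro")
>>> lf.species_formula(primer).hill()
'C48H91O20P'
>>> round(lf.precursor_mz(primer), 4)
1017.5769
>>> catalog = lf.full_catalog(primer)
>>> [(round(i.mz, 4), i.description) for i in catalog if i.n_cuts <= 1][:4]
[(73.0295, 'Gro - H3O'), (91.0401, 'Gro - H'),
 (152.9958, 'P-Gro - H3O'), (171.0064, 'P-Gro - H')]
>>> hits = lf.nominate_species(1017.58, "phosphoglycerol_153", tol=0.02)
>>> hits[0][0].shorthand()
'(30:0) DAG-Glc-Glc-P-Gro'
```

1017.5769 is the deprotonated molecular anion of the (30:0) primer;
152.9958 is its cyclic glycerophosphate diagnostic fragment; and the
nomination search correctly recovers the primer from its survey-scan m/z
plus the 153 channel.

From the shell, the same stages are:

```sh
ltafrag fragments "(30:0) DAG-Glc-Glc-P-Gro" -o primer_catalog.tsv
ltafrag annotate peaks.csv "(30:0) DAG-Glc-Glc-P-Gro" --tol 0.01 -o report.tsv
ltafrag simulate --seed 7 -o fullscan.mgf
ltafrag scan --diagnostic 88 --seed 7 -o alanylated_trace.csv
```

The annotation report lists observed m/z, nearest calculated m/z, signed
deviation, cleavage labels and a description per peak; unmatched peaks are
reported, never force-assigned.

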
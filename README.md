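# spice-composite

Spacing-preference screening for **transcription-factor composite
elements** from ChIP-Seq peaks.

Some transcription factors act cooperatively by binding DNA as pairs at
*composite elements*: two binding motifs that co-occur with a constrained
edge-to-edge spacing and relative orientation (classic examples are the
AP-1/IRF composite element, AICE, with its 0- or 4-bp spacing, and the
tandem GAS sites 11–12 bp apart that support STAT5 tetramers). This
package screens a ChIP-Seq experiment against a motif database and ranks
candidate partner motifs by how non-uniformly their best binding sites
distribute around the ChIP'd factor's own motif.

It is aimed at computational biologists with ChIP-Seq peak calls
(narrowPeak/BED), a reference genome FASTA, and a motif collection in MEME
or JASPAR format (e.g., HOCOMOCO).

## Method

1. **Windows.** The *n* most significant peaks (by narrowPeak
   −log₁₀ *p*) yield fixed-width (default 500 bp) sequence windows
   centered on peak summits.
2. **Primary motif.** Either discovered de novo by ZOOPS
   (zero-or-one-occurrence-per-sequence) EM over both strands, or supplied
   by name from the database. Windows without a match scoring ≥ 60 % of
   the motif's maximum log-odds are eliminated.
3. **Centering.** Each retained window is re-oriented so the best primary
   site reads on the forward strand and trimmed so the site sits exactly
   at the window center.
4. **Spacing scan.** For each secondary motif *s* in the database, the
   single best non-overlapping site per window is recorded as a spacing
   bin: an orientation quadrant (upstream/downstream × same/opposite
   strand) and the edge-to-edge gap in bp (gap 0 = abutting).
5. **Statistics.** Under the no-preference null the best site falls
   uniformly over the *B* available bins, so a bin's count *k* out of *n*
   windows is Binomial(*n*, 1/*B*). Each occupied bin gets an exact tail
   *p*-value P[X ≥ k], Bonferroni-adjusted by *B*; a pair's **E-value** is
   its best adjusted *p* times the database size. Pairs with adjusted
   *p* < 0.01 are ranked, redundant secondaries are collapsed by PFM
   correlation (single linkage), and many libraries aggregate into a
   sparse interaction matrix rendered as a −log₁₀(E) heat map.

## Worked example

Simulate an AICE-like dataset (AP-1 primary `TGASTCA`, IRF `TGAAAC`
secondary planted 4 bp downstream in 60 % of 1000 windows) and screen it:

```sh
spice simulate --preset aice --n 1000 --seed 7 --out sim/
spice spacing --windows sim/windows.fa --primary AP1 \
      --database sim/motifs.meme --alpha 0.01 --out pairs.tsv
```

`pairs.tsv` then contains:

```
primary	secondary	quadrant	gap	k	n	B	p_raw	p_adj	evalue
AP1	IRF	downstream-same	4	611	1000	964	1e-300	9.64e-298	1.928e-297
AP1	AP1	downstream-same	4	46	1000	960	1.570230160615574e-58	1.507420954190951e-55	3.014841908381902e-55
```

Read: of 1000 windows with an AP-1 anchor, 611 placed their best IRF site
in the same 1-bp bin — 4 bp downstream of the anchor, same strand —
against a uniform expectation of 1000/964 ≈ 1, an overwhelmingly
significant spacing preference recovering the planted 4-bp gap (the tail
*p* underflows and is floored at 1e-300). The weaker AP1–AP1 self-pair
row is a shadow of the planted composite: the IRF site's flank partially
matches AP-1 often enough to register. The same pipeline is driven over
real peak files with `spice run --config spice.yaml`, which chains
extraction, discovery, the screen, clustering and heat-map reporting.

From Python:

```python
from spice import analyze_pair
from spice.synthetic import generate_aice

windows, truth, ap1, irf = generate_aice(1000, seed=7)
result = analyze_pair(windows, ap1, irf)
print(result.best.bin.gap)   # 4
```

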
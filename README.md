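# nrpairs

Monomer-pair fingerprints for comparative analysis of nonribosomal
peptide (NRP) gene clusters.

Nonribosomal peptide synthetases (NRPS) are modular assembly lines: each
module incorporates one monomer — a proteinogenic or nonproteinogenic
amino acid, or, in hybrid NRPS–PKS systems, a polyketide unit — into the
growing product. Genome-mining tools predict the monomer loaded by each
module from adenylation-domain sequence, but whole predicted backbones
rarely match known compounds exactly: tailoring, substrate promiscuity
and prediction error all blur the picture. `nrpairs` works instead at
the level of **adjacent monomer pairs**, the smallest fragment whose
identity survives both biosynthetic variation and mass-spectrometric or
NMR observation. Biosynthetic patterns shared across species then show
up as pairs that recur in many gene clusters.

For whom: researchers doing comparative genome mining of NRPS/PKS gene
clusters who have per-module monomer predictions (antiSMASH-era output)
and want product-centered cross-species comparison without running
alignments.

## Method

1. **Consensus calling.** Each module carries calls from three
   specificity predictors (NRPSpredictor2, Stachelhaus code, Minowa). A
   monomer is accepted only on full agreement (a 2-of-3 policy is
   available); discordant modules become the unresolved token `nrp`.
2. **Fragmentation.** An ordered backbone `m₁ m₂ … m_L` is cut into its
   `L−1` adjacent pairs; each pair is normalized alphabetically
   (`val,ala → ala.val`). Pairs from predictions are **POPs**, pairs
   from known compound backbones are **PECs**. Unigrams and trigrams are
   available as alternative fragment sizes.
3. **Point matching.** Each POP is scored against a compound's PEC set,
   after pooling polyketide tokens (`mal`, `ohmal`, …) onto the class
   token `pk` on both sides: 1 point for an exact pair match, 0.5 when
   exactly one member is `nrp` and the other occurs in the PECs, 0
   otherwise. Per cluster, total points / number of POPs gives the
   fraction of correct prediction fragments, which is compared against
   the cluster's gene-level homology percentage.
4. **Similarity and patterns.** Instances (clusters or organisms) become
   binary fingerprints over the pair vocabulary; pairwise similarity is
   the Jaccard index J(A,B) = |A∩B| / |A∪B|; instances are grouped by
   average-linkage hierarchical clustering on Euclidean distances, and
   pair distributions are tabulated globally, per compound cohort, or
   per dendrogram branch. Organism→compound and organism→POP networks
   are exported for Cytoscape-class viewers (SIF/GraphML).

A synthetic-cohort generator produces record sets derived from a
template compound with identity-linked module corruption, so the whole
pipeline — including the identity-vs-correctness relationship — is
testable without any genome downloads.

## Worked example

Delftibactin (MIBiG BGC0000984), a hybrid NRPS–PKS metallophore, has the
nine-unit backbone `pk asp thr gly thr orn ser arg orn` (bundled with
the package). Scoring the six POPs reported for a Delftibactin-homolog
gene cluster of *Variovorax paradoxus*:

```python
from nrpairs import (load_compound_library, get_compound, pecs_for,
                     score_pops, PairMultiset)

delf = get_compound(load_compound_library(), "Delftibactin")
pecs = pecs_for(delf)
print("PECs:", ", ".join(f"{k} (x{v})" for k, v in sorted(pecs.counts.items())))

pops = PairMultiset(counts={k: 1 for k in
    ["nrp.pk", "ohmal.nrp", "ohmal.ser", "orn.ser", "orn.thr", "asp.thr"]},
    origin="V. paradoxus-C3")
score = score_pops(pops, delf)
for r in score.results:
    print(f"  {r.pop:<10} {r.points:>4}  ({r.match_kind})")
print(f"total {score.total_points} over {score.n_pops} POPs "
      f"-> fraction_correct {score.fraction_correct:.3f}")
```

prints

```
PECs: arg.orn (x1), arg.ser (x1), asp.pk (x1), asp.thr (x1), gly.thr (x2), orn.ser (x1), orn.thr (x1)
  asp.thr     1.0  (exact)
  nrp.pk      0.5  (partial_nrp)
  ohmal.nrp   0.5  (partial_nrp)
  ohmal.ser   0.0  (none)
  orn.ser     1.0  (exact)
  orn.thr     1.0  (exact)
total 4.0 over 6 POPs -> fraction_correct 0.667
```

`gly.thr (x2)` shows the pair occurring twice in the backbone;
`nrp.pk` earns half a point because its polyketide half is confirmed by
the `asp.pk` PEC while its other half was out of consensus; `ohmal.ser`
pools to `pk.ser`, a junction the compound does not contain, and scores
zero. Two thirds of this cluster's prediction fragments are correct.

The same analysis end-to-end, from a record file to all artifacts
(score reports, binary and Jaccard matrices, dendrogram, distribution
tables, networks, run manifest):

```bash
nrpairs simulate --out records.json --n-clusters 50 --seed 1
nrpairs run records.json --out-dir results/
```

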
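# Keyword rules for binning pathways into reporting categories.
# Per scheme: an ordered list of {keywords, category}; the first rule whose
# keyword (case-insensitive substring) hits the pathway name or description
# wins; pathways with no hit are labelled "unclassified".
# Rules are ordered most-specific-first.

neural8:
  - {keywords: [neurotransmitter], category: neurotransmitter secretion}
  - {keywords: [neural crest], category: neural crest development}
  - {keywords: [axon, dendrit], category: axon growth and dendrite pruning}
  - {keywords: [synap], category: synapse formation}
  - {keywords: [neuron projection, projection, neuron apopto, neuron death, apopto],
     category: neuron projection and apoptosis}
  - {keywords: [cns, central nervous, neural tube, neural plate, cortex, pallium,
                telencephalon, forebrain, brain, spinal cord],
     category: neural structure formation in CNS}
  - {keywords: [differentiation, neurogenesis, neuroblast, precursor, fate commitment],
     category: neuron differentiation}
  - {keywords: [glia, glio, schwann, astrocyte, myelin],
     category: development of glia}

# four developmental-order groups: early neural-plate events through late
# synaptic function
groups4:
  - {keywords: [fate commitment, neural plate, neural tube, tube closure],
     category: neural fate commitment and plate formation}
  - {keywords: [synap, neurotransmitter, neuron apopto, neuron death, apopto],
     category: "synapse formation, neurotransmitter secretion and neuron apoptosis"}
  - {keywords: [axon, dendrit, glia, glio, schwann, myelin],
     category: "axon growth, dendrite protrusion and glia differentiation"}
  - {keywords: [differentiation, migration, neuroblast, precursor, neurogenesis],
     category: neuron differentiation and migration}

nonneural_fig2:
  - {keywords: [cytokine, chemokine], category: cytokine production}
  - {keywords: [collagen], category: collagen synthesis}
  - {keywords: [adhesion, adherens], category: cell adhesion}
  - {keywords: [cell cycle, dna replication, mitotic, mitosis, chromosome segregation],
     category: cell cycle and DNA replication}
  - {keywords: [transcription, translation, ribosom, rna processing, splicing],
     category: transcription and translation}
  - {keywords: [immune, immunity, antigen, lymphocyte, t cell, b cell, interferon,
                inflammat],
     category: immune response}
  - {keywords: [organelle, golgi, mitochond, lysosom, peroxisom],
     category: organelle assembly}

nonneural_fig3:
  - {keywords: [cytokine, chemokine], category: cytokine and chemokine production}
  - {keywords: [calcium], category: calcium sequestering}
  - {keywords: [hemopoie, hematopoie, haemopoie], category: hemopoiesis}
  - {keywords: [extracellular matrix, ecm, collagen], category: ECM synthesis}
  - {keywords: [adhesion, adherens], category: cell adhesion}
  - {keywords: [endocyto], category: endocytosis}
  - {keywords: [dna damage, dna repair, dna metab, dna replication],
     category: DNA damage and metabolism}
  - {keywords: [skeleton, cytoskelet, actin, microtubule],
     category: cell skeleton synthesis}
  - {keywords: [organelle, golgi, mitochond, lysosom, peroxisom],
     category: organelle assembly}
  - {keywords: [cell death, apopto], category: regulation of cell death}
  - {keywords: [de-development, dedifferentiation, de-differentiation],
     category: de-development process}

# two super-classes of non-neural activity used for the stage-wise fractions
envclass2:
  - {keywords: [cytokine, chemokine, adhesion, adherens, calcium, hemopoie,
                hematopoie, haemopoie, extracellular matrix, ecm, collagen],
     category: cell-environment interaction}
  - {keywords: [skeleton, cytoskelet, actin, microtubule, dna damage, dna repair,
                dna metab, organelle, golgi, mitochond, lysosom],
     category: intracellular damage processing}
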
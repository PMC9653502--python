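# Diagnosis-conditioned concept tables for the synthetic cohort generator.
#
# For each diagnosis label (a class id in mini_ontology.json), each category
# lists the canonical finding concepts drawn for a patient carrying that
# diagnosis, with an independent inclusion probability. Microscopy entries may
# carry `locations`: class ids co-mentioned as "finding in location"
# composites, exercising the compositional matcher. The `background` block
# applies to every patient regardless of diagnosis.
#
# These are qualitative stand-ins for the unpublished cohort frequencies:
# microscopy deliberately carries the dominant diagnostic signal, imaging a
# moderate one, immunohistochemistry less, and anatomy the least.

label_prevalence:   # single-diagnosis counts of the source cohort (n = 310 of 315)
  HippocampalSclerosis: 36
  GliosisWithoutHS: 10
  MalformationOfCorticalDevelopment: 136
  BrainTumor: 81
  Gliosis: 20
  Encephalitis: 11
  Cyst: 3
  Encephalopathy: 2
  Cavernoma: 2
  AlzheimersDisease: 1
  ArteriovenousMalformation: 1
  NotOtherwiseSpecified: 7

diagnoses:
  HippocampalSclerosis:
    microscopy:
      - {concept: NeuronalLoss, p: 0.95, locations: [CA1, CA2, CA3, CA4]}
      - {concept: Astrogliosis, p: 0.7, locations: [CA1, CA4]}
      - {concept: GranuleCellDispersion, p: 0.4, locations: [DentateGyrus]}
      - {concept: SevereNeuronalLoss, p: 0.3}
      - {concept: FibrillaryAstrogliosis, p: 0.25}
    immunohistochemistry:
      - {concept: NeuN, p: 0.4}
      - {concept: GFAP, p: 0.4}
    imaging:
      - {concept: HippocampalAtrophy, p: 0.85}
      - {concept: IncreasedT2Signal, p: 0.5}
    anatomy:
      - {concept: Hippocampus, p: 0.9}
      - {concept: TemporalLobe, p: 0.5}
  GliosisWithoutHS:
    microscopy:
      - {concept: ReactiveGliosis, p: 0.9}
      - {concept: NoNeuronalLoss, p: 0.8}
    immunohistochemistry:
      - {concept: GFAP, p: 0.5}
    imaging:
      - {concept: NormalMRI, p: 0.6}
    anatomy:
      - {concept: Hippocampus, p: 0.8}
  MalformationOfCorticalDevelopment:
    microscopy:
      - {concept: CorticalDyslamination, p: 0.9, locations: [Neocortex, TemporalLobe, FrontalLobe]}
      - {concept: DysmorphicNeuron, p: 0.65}
      - {concept: BalloonCell, p: 0.45}
      - {concept: NodularHeterotopia, p: 0.2}
      - {concept: Polymicrogyria, p: 0.1}
    immunohistochemistry:
      - {concept: Vimentin, p: 0.3}
      - {concept: PhosphoS6RibosomalProtein, p: 0.2}
      - {concept: NeuN, p: 0.3}
      - {concept: MAP2, p: 0.2}
    imaging:
      - {concept: CorticalThickening, p: 0.55}
      - {concept: BlurredGrayWhiteJunction, p: 0.55}
      - {concept: TransmantleSign, p: 0.25}
      - {concept: FLAIRHyperintensity, p: 0.4}
    anatomy:
      - {concept: FrontalLobe, p: 0.4}
      - {concept: TemporalLobe, p: 0.4}
      - {concept: Neocortex, p: 0.25}
  BrainTumor:
    microscopy:
      - {concept: GanglionCell, p: 0.65}
      - {concept: MitoticFigures, p: 0.5}
      - {concept: Rosette, p: 0.3}
      - {concept: Calcification, p: 0.3}
      - {concept: AngiocentricPattern, p: 0.2}
      - {concept: Necrosis, p: 0.2}
    immunohistochemistry:
      - {concept: Ki67, p: 0.45}
      - {concept: CD34, p: 0.35}
      - {concept: OLIG2, p: 0.25}
      - {concept: Synaptophysin, p: 0.25}
      - {concept: GFAP, p: 0.3}
      - {concept: BRAFV600E, p: 0.15}
      - {concept: IDH1R132H, p: 0.1}
    imaging:
      - {concept: MassLesion, p: 0.8}
      - {concept: ContrastEnhancement, p: 0.5}
      - {concept: CysticLesion, p: 0.3}
    anatomy:
      - {concept: TemporalLobe, p: 0.6}
      - {concept: FrontalLobe, p: 0.3}
  Gliosis:
    microscopy:
      - {concept: ReactiveGliosis, p: 0.9, locations: [WhiteMatter, TemporalLobe]}
      - {concept: FibrillaryAstrogliosis, p: 0.3}
    immunohistochemistry:
      - {concept: GFAP, p: 0.6}
    imaging:
      - {concept: FLAIRHyperintensity, p: 0.4}
    anatomy:
      - {concept: WhiteMatter, p: 0.4}
      - {concept: TemporalLobe, p: 0.3}
  Encephalitis:
    microscopy:
      - {concept: PerivascularLymphocyticInfiltrate, p: 0.95}
      - {concept: MicrogliaActivation, p: 0.7}
      - {concept: Granuloma, p: 0.15}
    immunohistochemistry:
      - {concept: CD3, p: 0.5}
      - {concept: CD8, p: 0.35}
    imaging:
      - {concept: FLAIRHyperintensity, p: 0.5}
      - {concept: BrainSwelling, p: 0.3}
    anatomy:
      - {concept: TemporalLobe, p: 0.4}
      - {concept: Insula, p: 0.3}
  Cyst:
    microscopy:
      - {concept: CystWall, p: 0.9}
    immunohistochemistry:
      - {concept: EMA, p: 0.3}
    imaging:
      - {concept: CysticLesion, p: 0.9}
    anatomy:
      - {concept: TemporalLobe, p: 0.3}
  Encephalopathy:
    microscopy:
      - {concept: NeuronalLoss, p: 0.5, locations: [Neocortex]}
      - {concept: ReactiveGliosis, p: 0.6}
    imaging:
      - {concept: CerebralAtrophy, p: 0.7}
    anatomy:
      - {concept: Neocortex, p: 0.5}
  Cavernoma:
    microscopy:
      - {concept: Hemosiderin, p: 0.9}
      - {concept: VascularMalformationFinding, p: 0.8}
    imaging:
      - {concept: FlowVoid, p: 0.5}
      - {concept: MassLesion, p: 0.3}
    anatomy:
      - {concept: FrontalLobe, p: 0.4}
  AlzheimersDisease:
    microscopy:
      - {concept: NeurofibrillaryTangles, p: 0.9}
      - {concept: AmyloidPlaques, p: 0.9}
    immunohistochemistry:
      - {concept: TauProtein, p: 0.6}
      - {concept: BetaAmyloid, p: 0.6}
    anatomy:
      - {concept: Hippocampus, p: 0.5}
  ArteriovenousMalformation:
    microscopy:
      - {concept: VascularMalformationFinding, p: 0.9}
    imaging:
      - {concept: FlowVoid, p: 0.8}
    anatomy:
      - {concept: ParietalLobe, p: 0.4}
  NotOtherwiseSpecified:
    microscopy:
      - {concept: NonspecificChanges, p: 0.8}
    imaging:
      - {concept: NormalMRI, p: 0.4}
    anatomy:
      - {concept: TemporalLobe, p: 0.3}

background:
  microscopy:
    - {concept: NonspecificChanges, p: 0.08}
  immunohistochemistry:
    - {concept: GFAP, p: 0.25}
    - {concept: NeuN, p: 0.2}
    - {concept: Ki67, p: 0.15}
  imaging:
    - {concept: IncreasedT2Signal, p: 0.1}
  anatomy:
    - {concept: TemporalLobe, p: 0.15}
    - {concept: Amygdala, p: 0.08}
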
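# Default criteria tree for prioritizing high-impact health technologies in a
# regional health service. Five domains, fifteen criteria, fifteen subcriteria.
# Nodes marked `placeholder: true` fill positions whose exact labels were not
# published; their labels follow EVIDEM-style conventions and are meant to be
# replaced by users with their own validated criteria set. This file is data,
# not code: edit or swap it freely.
name: regional-high-impact-default
version: "1.0"
domains:
  - id: d1
    label: Need for intervention
    description: >
      How pressing the health problem is: the size of the affected
      population, the severity of the disease, and the extent to which
      current care leaves needs unmet.
    criteria:
      - id: d1.c1
        label: Affected population
        description: >
          Size of the population affected by the condition the technology
          targets, combining how frequently new cases arise and how many
          people live with the condition.
        subcriteria:
          - id: d1.c1.s1
            label: Disease incidence
            placeholder: true
            description: Rate of new cases of the target condition. Placeholder label.
          - id: d1.c1.s2
            label: Disease prevalence
            placeholder: true
            description: Number of people living with the target condition. Placeholder label.
      - id: d1.c2
        label: Disease severity
        description: >
          Burden of the condition on survival, disability, and daily life in
          the absence of the intervention under evaluation.
      - id: d1.c3
        label: Unmet needs
        placeholder: true
        description: >
          Limitations of currently available care, in health-related quality
          of life and in convenience of treatment. Placeholder grouping label.
        subcriteria:
          - id: d1.c3.s1
            label: Unmet needs in HRQoL
            description: >
              Shortfall in health-related quality of life that existing
              interventions leave unaddressed.
          - id: d1.c3.s2
            label: Unmet needs in convenience
            description: >
              Burden of administration, monitoring, or access that existing
              interventions impose on patients and carers.
  - id: d2
    label: Outcomes of the intervention
    description: >
      What the technology achieves for patients relative to the best
      available comparator: effectiveness, safety, patient-perceived
      outcomes, and the type of benefit it delivers.
    criteria:
      - id: d2.c1
        label: Comparative effectiveness
        placeholder: true
        description: >
          Improvement in clinical outcomes relative to the comparator.
          Placeholder label.
        subcriteria:
          - id: d2.c1.s1
            label: Change in intermediate outcomes
            description: >
              Effect on surrogate or intermediate clinical endpoints relative
              to the comparator.
          - id: d2.c1.s2
            label: Change in mortality
            placeholder: true
            description: Effect on survival relative to the comparator. Placeholder label.
      - id: d2.c2
        label: Comparative safety
        description: >
          Harms of the technology relative to the comparator.
        subcriteria:
          - id: d2.c2.s1
            label: Frequency of adverse events
            placeholder: true
            description: How often undesirable effects occur. Placeholder label.
          - id: d2.c2.s2
            label: Severity of adverse events
            placeholder: true
            description: How serious the undesirable effects are. Placeholder label.
      - id: d2.c3
        label: Patient-perceived outcomes
        description: >
          Outcomes as experienced and reported by patients, beyond clinical
          endpoints.
        subcriteria:
          - id: d2.c3.s1
            label: Change in HRQoL
            description: >
              Effect on health-related quality of life as perceived by
              patients.
          - id: d2.c3.s2
            label: Change in convenience
            description: >
              Effect on the ease of use, administration burden, and fit with
              patients' daily lives.
      - id: d2.c4
        label: Type of benefit
        description: >
          Nature of the benefit the technology provides, distinguishing
          prevention from treatment of established disease.
        subcriteria:
          - id: d2.c4.s1
            label: Preventive benefit
            description: Capacity of the technology to avoid or delay disease.
          - id: d2.c4.s2
            label: Therapeutic benefit
            description: Capacity of the technology to treat established disease.
  - id: d3
    label: Knowledge of the intervention
    description: >
      How well the effects of the technology are known: the quality and
      relevance of the supporting evidence and the degree of expert
      consensus.
    criteria:
      - id: d3.c1
        label: Quality of the evidence
        description: >
          Internal validity, completeness, and consistency of the evidence
          supporting the technology's claimed effects.
      - id: d3.c2
        label: Expert consensus
        description: >
          Degree of agreement among clinical experts and practice guidelines
          on the use of the technology.
      - id: d3.c3
        label: Relevance of the evidence
        placeholder: true
        description: >
          Applicability of the available evidence to the local decision
          context. Placeholder label.
  - id: d4
    label: Economic impact
    description: >
      Consequences of adopting the technology for healthcare and
      non-healthcare budgets, including what must be given up elsewhere.
    criteria:
      - id: d4.c1
        label: Non-medical costs
        description: >
          Costs falling outside the healthcare system, such as social care
          and productivity losses.
        subcriteria:
          - id: d4.c1.s1
            label: Informal care costs
            placeholder: true
            description: >
              Costs borne by patients and unpaid carers. Placeholder label.
      - id: d4.c2
        label: Opportunity costs and budget impact
        description: >
          Net effect on the health budget and the value of the services
          displaced to fund the technology.
        subcriteria:
          - id: d4.c2.s1
            label: Impact on the intervention budget
            placeholder: true
            description: Direct budget impact of acquiring and operating the technology. Placeholder label.
          - id: d4.c2.s2
            label: Impact on other healthcare budgets
            placeholder: true
            description: Knock-on costs or savings elsewhere in the system. Placeholder label.
      - id: d4.c3
        label: Comparative cost-effectiveness
        placeholder: true
        description: >
          Efficiency of the technology relative to the comparator.
          Placeholder label.
  - id: d5
    label: Feasibility
    description: >
      Capacity of the health system to adopt the technology: resources,
      infrastructure, training, and organizational consequences.
    criteria:
      - id: d5.c1
        label: System capacity and resources
        placeholder: true
        description: >
          Availability of the staff, equipment, and infrastructure the
          technology requires. Placeholder label.
      - id: d5.c2
        label: Organizational impact
        placeholder: true
        description: >
          Changes to care pathways, workflows, and service organization that
          adoption entails. Placeholder label.
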
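# Demonstration symptom lexicon (~28 canonicals).
# Surface forms are lay terms as they appear in web-scraped narratives;
# variants of one symptom are merged into its canonical column.
canonical: auditory hallucination
  variant: auditory hallucination
  variant: auditory hallucinations
  variant: hearing voices
  variant: hear voices
  variant: heard voices
canonical: visual hallucination
  variant: visual hallucination
  variant: visual hallucinations
  variant: seeing things
canonical: schizophrenia
  variant: schizophrenia
  variant: schizophrenic
canonical: fear
  variant: fear
  variant: fears
  variant: fearful
  variant: afraid
  variant: scared
canonical: delusion
  variant: delusion
  variant: delusions
  variant: delusional
canonical: psychosis
  variant: psychosis
  variant: psychotic
canonical: paranoia
  variant: paranoia
  variant: paranoid
canonical: suicide
  variant: suicide
  variant: suicidal
canonical: pain
  variant: pain
  variant: painful
  variant: aching
canonical: trauma
  variant: trauma
  variant: traumatic
  variant: traumatised
  variant: traumatized
canonical: depression
  variant: depression
  variant: depressed
  variant: depressive
canonical: anxiety
  variant: anxiety
  variant: anxious
  variant: anxiousness
canonical: loneliness
  variant: loneliness
  variant: lonely
canonical: low mood
  variant: low mood
canonical: lethargy
  variant: lethargy
  variant: lethargic
canonical: lack of sleep
  variant: lack of sleep
  variant: sleep at night
  variant: insomnia
  variant: sleepless
canonical: panic attacks
  variant: panic attacks
  variant: panic attack
canonical: dissociation
  variant: dissociation
  variant: dissociative
  variant: dissociating
canonical: obsession
  variant: obsession
  variant: obsessions
  variant: obsessive
canonical: compulsion
  variant: compulsion
  variant: compulsions
  variant: compulsive
canonical: hypertension
  variant: hypertension
  variant: high blood pressure
canonical: nausea
  variant: nausea
  variant: nauseous
canonical: weight loss
  variant: weight loss
  variant: losing weight
canonical: head
  variant: head
  variant: headache
  variant: headaches
canonical: sadness
  variant: sadness
  variant: sad
canonical: apprehensions
  variant: apprehensions
  variant: apprehension
canonical: anger
  variant: anger
  variant: angry
canonical: stress
  variant: stress
  variant: stressed
[blacklist]
the
and
but
with
have
this
that
from
they
them
when
then
just
like
very
often
always
feel
felt
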
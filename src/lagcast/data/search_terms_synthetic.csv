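category,term
suicide_seeking,commit suicide
suicide_seeking,how to commit suicide
suicide_seeking,how to kill myself
suicide_seeking,kill myself
suicide_seeking,want to die
suicide_seeking,ways to kill yourself
suicide_seeking,painless suicide
suicide_seeking,easy suicide
suicide_seeking,suicide methods
suicide_seeking,how to hang yourself
suicide_seeking,overdose to die
suicide_seeking,end my life
suicide_seeking,i want to kill myself
suicide_seeking,best way to kill yourself
suicide_seeking,quick suicide
suicide_seeking,how to die
suicide_seeking,lethal dose
suicide_seeking,take my own life
suicide_prevention,suicide hotline
suicide_prevention,suicide prevention
suicide_prevention,crisis hotline
suicide_prevention,crisis line
suicide_prevention,suicide help
suicide_prevention,suicidal help
suicide_prevention,suicide counseling
suicide_prevention,help for depression
suicide_prevention,suicide support
suicide_prevention,suicide prevention lifeline
suicide_prevention,talk to someone
suicide_prevention,mental health help
suicide_prevention,stop suicidal thoughts
suicide_prevention,suicide warning signs
suicide_prevention,how to help a suicidal friend
suicide_neutral,suicide
suicide_neutral,suicides
suicide_neutral,suicidal
suicide_neutral,suicide rate
suicide_neutral,suicide statistics
suicide_neutral,suicide deaths
suicide_neutral,celebrity suicide
suicide_neutral,suicide news
suicide_neutral,suicide note
suicide_neutral,attempted suicide
suicide_neutral,suicide attempt
suicide_neutral,teen suicide
suicide_neutral,suicide in america
suicide_neutral,physician assisted suicide
suicide_neutral,suicide definition
mood_anxiety,depressed
mood_anxiety,depression
mood_anxiety,am i depressed
mood_anxiety,depression symptoms
mood_anxiety,depression test
mood_anxiety,major depression
mood_anxiety,clinical depression
mood_anxiety,feeling hopeless
mood_anxiety,hopelessness
mood_anxiety,sadness
mood_anxiety,feeling empty
mood_anxiety,worthless
mood_anxiety,anxiety
mood_anxiety,anxiety attack
mood_anxiety,panic attack
mood_anxiety,anxiety symptoms
mood_anxiety,social anxiety
mood_anxiety,generalized anxiety disorder
mood_anxiety,anxiety disorder
mood_anxiety,stress and anxiety
mood_anxiety,bipolar
mood_anxiety,bipolar disorder
mood_anxiety,manic depression
mood_anxiety,mood swings
mood_anxiety,mental breakdown
mood_anxiety,nervous breakdown
mood_anxiety,antidepressant
mood_anxiety,insomnia depression
mood_anxiety,crying for no reason
mood_anxiety,cant sleep depressed
psychosis,delusion
psychosis,delusions
psychosis,hallucination
psychosis,hallucinations
psychosis,hearing voices
psychosis,psychosis
psychosis,psychotic
psychosis,schizophrenia
psychosis,schizophrenia symptoms
psychosis,paranoia
psychosis,paranoid
psychosis,psychotic break
psychosis,schizoaffective disorder
stressor_trauma,social isolation
stressor_trauma,loneliness
stressor_trauma,lonely
stressor_trauma,grief
stressor_trauma,bereavement
stressor_trauma,lost my job
stressor_trauma,unemployment stress
stressor_trauma,divorce
stressor_trauma,breakup
stressor_trauma,heartbroken
stressor_trauma,bullying
stressor_trauma,cyberbullying
stressor_trauma,abuse
stressor_trauma,domestic violence
stressor_trauma,ptsd
stressor_trauma,trauma
stressor_trauma,traumatic stress
stressor_trauma,financial problems
stressor_trauma,debt stress
stressor_trauma,chronic pain
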
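item_id,subscale,response,score
q1,general_health,1,100
q1,general_health,2,75
q1,general_health,3,50
q1,general_health,4,25
q1,general_health,5,0
q2,general_vision,1,100
q2,general_vision,2,80
q2,general_vision,3,60
q2,general_vision,4,40
q2,general_vision,5,20
q2,general_vision,6,0
q3,mental_health,1,100
q3,mental_health,2,75
q3,mental_health,3,50
q3,mental_health,4,25
q3,mental_health,5,0
q4,ocular_pain,1,100
q4,ocular_pain,2,75
q4,ocular_pain,3,50
q4,ocular_pain,4,25
q4,ocular_pain,5,0
q5,near_activities,1,100
q5,near_activities,2,75
q5,near_activities,3,50
q5,near_activities,4,25
q5,near_activities,5,0
q5,near_activities,6,
q6,near_activities,1,100
q6,near_activities,2,75
q6,near_activities,3,50
q6,near_activities,4,25
q6,near_activities,5,0
q6,near_activities,6,
q7,near_activities,1,100
q7,near_activities,2,75
q7,near_activities,3,50
q7,near_activities,4,25
q7,near_activities,5,0
q7,near_activities,6,
q8,distance_activities,1,100
q8,distance_activities,2,75
q8,distance_activities,3,50
q8,distance_activities,4,25
q8,distance_activities,5,0
q8,distance_activities,6,
q9,distance_activities,1,100
q9,distance_activities,2,75
q9,distance_activities,3,50
q9,distance_activities,4,25
q9,distance_activities,5,0
q9,distance_activities,6,
q10,peripheral_vision,1,100
q10,peripheral_vision,2,75
q10,peripheral_vision,3,50
q10,peripheral_vision,4,25
q10,peripheral_vision,5,0
q10,peripheral_vision,6,
q11,social_functioning,1,100
q11,social_functioning,2,75
q11,social_functioning,3,50
q11,social_functioning,4,25
q11,social_functioning,5,0
q11,social_functioning,6,
q12,color_vision,1,100
q12,color_vision,2,75
q12,color_vision,3,50
q12,color_vision,4,25
q12,color_vision,5,0
q12,color_vision,6,
q13,social_functioning,1,100
q13,social_functioning,2,75
q13,social_functioning,3,50
q13,social_functioning,4,25
q13,social_functioning,5,0
q13,social_functioning,6,
q14,distance_activities,1,100
q14,distance_activities,2,75
q14,distance_activities,3,50
q14,distance_activities,4,25
q14,distance_activities,5,0
q14,distance_activities,6,
q15c,driving,1,100
q15c,driving,2,75
q15c,driving,3,50
q15c,driving,4,25
q15c,driving,5,0
q16,driving,1,100
q16,driving,2,75
q16,driving,3,50
q16,driving,4,25
q16,driving,5,0
q16,driving,6,
q16a,driving,1,100
q16a,driving,2,75
q16a,driving,3,50
q16a,driving,4,25
q16a,driving,5,0
q16a,driving,6,
q17,role_difficulties,1,0
q17,role_difficulties,2,25
q17,role_difficulties,3,50
q17,role_difficulties,4,75
q17,role_difficulties,5,100
q18,role_difficulties,1,0
q18,role_difficulties,2,25
q18,role_difficulties,3,50
q18,role_difficulties,4,75
q18,role_difficulties,5,100
q19,ocular_pain,1,0
q19,ocular_pain,2,25
q19,ocular_pain,3,50
q19,ocular_pain,4,75
q19,ocular_pain,5,100
q20,dependency,1,0
q20,dependency,2,25
q20,dependency,3,50
q20,dependency,4,75
q20,dependency,5,100
q21,mental_health,1,0
q21,mental_health,2,25
q21,mental_health,3,50
q21,mental_health,4,75
q21,mental_health,5,100
q22,mental_health,1,0
q22,mental_health,2,25
q22,mental_health,3,50
q22,mental_health,4,75
q22,mental_health,5,100
q23,dependency,1,0
q23,dependency,2,25
q23,dependency,3,50
q23,dependency,4,75
q23,dependency,5,100
q24,dependency,1,0
q24,dependency,2,25
q24,dependency,3,50
q24,dependency,4,75
q24,dependency,5,100
q25,mental_health,1,0
q25,mental_health,2,25
q25,mental_health,3,50
q25,mental_health,4,75
q25,mental_health,5,100
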
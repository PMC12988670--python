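# Default questionnaire map: 43 items drawn from four source questionnaires.
# Items belonging to a subscale are scored together (unweighted mean of the
# answered member items); every other item is its own QoL aspect, giving
# 37 aspects in total.  `level1_best: true` means response level 1 is the
# most favourable answer before 0-100 standardization.
items:
  # --- retained NEI-VFQ-25 subscale items -------------------------------
  - id: nei_driving_daylight
    levels: 5
    level1_best: true
    subscale: driving
    missing_codes: [6]   # stopped driving for non-visual reasons
  - id: nei_driving_night
    levels: 5
    level1_best: true
    subscale: driving
    missing_codes: [6]
  - id: nei_driving_difficult_conditions
    levels: 5
    level1_best: true
    subscale: driving
    missing_codes: [6]
  - id: nei_near_reading_print
    levels: 5
    level1_best: true
    subscale: near_activities
  - id: nei_near_fine_work
    levels: 5
    level1_best: true
    subscale: near_activities
  - id: nei_near_finding_objects
    levels: 5
    level1_best: true
    subscale: near_activities
  - id: nei_distance_reading_signs
    levels: 5
    level1_best: true
    subscale: distance_activities
  - id: nei_distance_stairs_dim_light
    levels: 5
    level1_best: true
    subscale: distance_activities
  - id: nei_social_seeing_reactions
    levels: 5
    level1_best: true
    subscale: social_functioning
  - id: nei_social_visiting
    levels: 5
    level1_best: true
    subscale: social_functioning
  # --- standalone NEI-VFQ-25 items --------------------------------------
  - id: nei_general_health
    levels: 5
    level1_best: true
  - id: nei_general_vision
    levels: 6
    level1_best: true
  - id: nei_ocular_pain
    levels: 5
    level1_best: true
  - id: nei_peripheral_vision
    levels: 5
    level1_best: true
  - id: nei_color_vision
    levels: 5
    level1_best: true
  # --- GQL-15 items ------------------------------------------------------
  - {id: gql_reading_newspaper, levels: 5, level1_best: true}
  - {id: gql_walking_after_dark, levels: 5, level1_best: true}
  - {id: gql_seeing_at_night, levels: 5, level1_best: true}
  - {id: gql_walking_uneven_ground, levels: 5, level1_best: true}
  - {id: gql_adjusting_bright_lights, levels: 5, level1_best: true}
  - {id: gql_adjusting_dim_lights, levels: 5, level1_best: true}
  - {id: gql_going_from_light_to_dark, levels: 5, level1_best: true}
  - {id: gql_tripping_over_objects, levels: 5, level1_best: true}
  - {id: gql_seeing_objects_from_side, levels: 5, level1_best: true}
  - {id: gql_crossing_the_road, levels: 5, level1_best: true}
  - {id: gql_walking_on_steps, levels: 5, level1_best: true}
  - {id: gql_bumping_into_objects, levels: 5, level1_best: true}
  - {id: gql_judging_distance_on_stairs, levels: 5, level1_best: true}
  - {id: gql_finding_dropped_objects, levels: 5, level1_best: true}
  - {id: gql_recognizing_faces, levels: 5, level1_best: true}
  # --- neuro-ophthalmology supplement items -----------------------------
  - {id: neuro_vision_differs_between_eyes, levels: 5, level1_best: true}
  - {id: neuro_eyelid_droop, levels: 5, level1_best: true}
  - {id: neuro_eye_looks_unusual, levels: 5, level1_best: true}
  - {id: neuro_double_vision, levels: 5, level1_best: true}
  - {id: neuro_light_sensitivity, levels: 5, level1_best: true}
  # --- luminance questionnaire items ------------------------------------
  - {id: lum_seeing_in_twilight, levels: 7, level1_best: true}
  - {id: lum_seeing_in_darkness, levels: 7, level1_best: true}
  - {id: lum_seeing_in_bright_sunlight, levels: 7, level1_best: true}
  - {id: lum_glare_oncoming_headlights, levels: 7, level1_best: true}
  - {id: lum_entering_dark_room, levels: 7, level1_best: true}
  - {id: lum_leaving_dark_room, levels: 7, level1_best: true}
  - {id: lum_reading_in_low_light, levels: 7, level1_best: true}
  - {id: lum_contrast_grey_weather, levels: 7, level1_best: true}
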
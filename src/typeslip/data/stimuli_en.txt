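the committee agreed that the new library building would open to the public early in the spring of next year
many of the students found that practice and patience were far more important than natural talent when learning to play the piano
after the long drought the farmers in the valley were relieved to see heavy rain falling steadily through the night
she explained that the results of the experiment could not be trusted until the measurements had been repeated several times
the old bridge across the river was closed for repairs so the morning traffic moved slowly through the narrow streets
according to the report the number of people cycling to work in the city has almost doubled over the last ten years
he thought that the meeting would finish before lunch but the discussion continued well into the afternoon
the small museum near the harbour keeps a remarkable collection of photographs from the early days of the fishing industry
when the power failed during the storm the family lit candles and told stories around the kitchen table until midnight
the doctor advised him to take gentle exercise every day and to avoid sitting at his desk for hours without a break
a thin layer of snow covered the garden and the children ran outside before breakfast to build a snowman
the journalist spent three months travelling through the region gathering interviews for her book about village life
it was clear from the first rehearsal that the orchestra needed more time to prepare the difficult second movement
the council promised that the damaged playground equipment would be replaced before the start of the summer holidays
most visitors climb the tower for the view but few notice the carved stone figures above the western door
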
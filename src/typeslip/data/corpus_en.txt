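the morning train was late again and the platform slowly filled with people reading the news on their phones
she poured the tea and watched the rain run down the kitchen window while the kettle cooled on the stove
most people think that learning a new language is a thing best started young but adults can make steady progress too
the report shows that the number of visitors to the national parks has been growing for the third year running
he packed the last of the boxes and carried them down the narrow stairs to the waiting van in the street
there is nothing quite like the smell of fresh bread drifting from the bakery on a cold winter morning
the teacher asked the children to write a short story about something kind they had done during the holidays
after dinner they walked along the beach and watched the fishing boats coming back into the harbour with the tide
the committee will meet on thursday to discuss the budget for the coming year and the plans for the new hall
it is important to drink plenty of water when working outside in the heat of the summer months
the engineers checked every bolt on the bridge before the road was opened to traffic again in the evening
her grandmother kept a small garden behind the house where she grew beans and carrots and sweet red tomatoes
the film starts at eight so we should leave the house no later than half past seven to find good seats
many birds travel thousands of miles every autumn to spend the winter in warmer countries far to the south
he was thinking about the letter all day and in the end he decided to answer it honestly and at once
the library is open every day except sunday and the reading room upstairs is quiet in the early afternoon
scientists have found that regular sleep makes a real difference to memory and attention in people of all ages
the market in the square sells cheese and flowers and second hand books every saturday morning until noon
she turned the key slowly and pushed the heavy door open into the dark and silent hallway of the old house
the recipe calls for two eggs a cup of flour and a little butter melted gently over a low flame
when the bus finally arrived it was so full that we decided to walk the rest of the way into town
the company announced that it would build a new factory near the port creating several hundred jobs
the children were singing in the next room and the sound carried softly through the whole house
nothing in the box had been touched for years and a thin layer of dust covered the photographs inside
the doctor listened carefully and then explained the treatment in plain words that were easy to understand
we should bring something warm to wear because the evenings in the mountains can be surprisingly cold
the string quartet played for nearly two hours and the audience stood to applaud at the end of the night
he wrote the address on the back of an envelope and promised to send the parcel the following morning
the path through the forest was marked with small wooden signs nailed to the trunks of the tallest trees
thinking it over again she realised that the first answer had been the right one all along
the team worked through the weekend to finish the project before the deadline on monday morning
a strong wind came up in the afternoon and the sailors decided to stay in the harbour until it passed
the museum has a new exhibition about the history of printing and the making of early books
everything on the menu looked good but in the end they both ordered the soup and the roast chicken
the nurse took his temperature and noted the reading on the chart at the foot of the bed
there was a long queue outside the theatre and the tickets were sold out within the first hour
the students spent the morning in the laboratory measuring the growth of the plants under different lights
it rained during the night and the streets were still shining when the first shops opened their doors
his brother works on the railway and knows the timetable of every train that passes through the station
the old clock in the hall strikes the hour with a deep and steady note that can be heard upstairs
she keeps the letters in a wooden box on the shelf above the desk in the corner of the study
the bright morning light filled the room and warmed the table where breakfast was already waiting
they planted an apple tree in the middle of the lawn on the day their daughter was born
the minister answered the question briefly and then turned to the subject of the new schools
the baker starts work long before dawn so that the first loaves are ready when the town wakes
something about the quiet street made him stop and look back at the house one more time
the meeting ended early and everyone agreed that the new plan was better than the old one
the river rises in the hills to the north and reaches the sea after a journey of eighty miles
hardly anything grows on the high ridge except tough grass and a few small twisted pines
the shop on the corner sells stamps and newspapers and is open until late in the evening
reading in bad light will tire your eyes but it will not damage them in any lasting way
the singer thanked the crowd and promised to return to the city the following spring
their house stands at the end of the lane behind a tall hedge and a white wooden gate
the first thing she does every morning is open the window and listen to the birds in the garden
the printer is out of paper again so the report will have to wait until the afternoon
he learned to swim in the cold water of the lake the summer he turned seven years old
the bell rang twice and the children gathered their books and hurried out into the yard
nobody remembered exactly when the tradition began but the whole village kept it faithfully
the road climbs steeply for three miles and then drops gently into the green valley beyond
she sharpened the pencil took a clean sheet of paper and began to draw the bowl of fruit
the soup needs a little more salt and perhaps a spoonful of cream just before serving
the last light of the day caught the tops of the towers and turned the windows to gold
every thing in the workshop had its place and the tools hung in neat rows along the wall
the train to the coast leaves from the far platform at ten minutes past the hour
his answer was short and honest and the interviewer thanked him and moved on to the next question
the garden was full of the sound of bees working among the flowers in the warm afternoon
think carefully before you sign the papers and ask about anything that seems unclear
the ship sailed at dawn with a light wind from the west and a calm sea ahead of her
they sat on the bench by the pond and shared the sandwiches they had brought from home
the young doctor moved to the village in the spring and stayed there for forty years
the thought of the long journey home made the evening seem shorter than it really was
a good map and a pair of strong boots are all you need to enjoy the hills in autumn
the clerk stamped the form smiled politely and pointed the way to the second floor
the letters were tied with string and arranged by date in the bottom drawer of the desk
nothing was decided at the first meeting but everyone left with plenty to think about
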